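"""Mechanical coupling: cell-gradient-driven linear elasticity and the
stress damping of tumor-cell diffusivity.

The displacement field solves

    div(G grad u) + grad[(G / (1 - 2 nu)) div u] - lam * grad N = 0

on the breast domain with zero displacement on (and outside) the mask
boundary, discretized with second-order central differences.  Stress is
recovered from the strain via linear isotropic elasticity with the same
moduli (shear modulus G = E / (2 (1 - nu)), Lame parameter
2 G nu / (1 - 2 nu)), and the von Mises invariant of that stress damps the
baseline diffusivity exponentially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, lgmres, spilu, splu

from .grid import BreastDomain, ImageVolume, StudyConfig
from .quantities import CellularityMap

__all__ = [
    "MaterialField",
    "MechanicalState",
    "material_field_from_domain",
    "solve_equilibrium",
    "von_mises",
    "damp_diffusion",
]


@dataclass(frozen=True)
class MaterialField:
    """Per-voxel Young's modulus with scalar Poisson ratio and coupling."""

    young_modulus: ImageVolume  # kPa
    poisson_ratio: float = 0.45
    coupling: float = 2.5e-3

    def __post_init__(self) -> None:
        if not self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be < 0.5")

    @property
    def shear_modulus(self) -> np.ndarray:
        """G = E / (2 (1 - nu)) in kPa."""
        return self.young_modulus.values / (2.0 * (1.0 - self.poisson_ratio))


@dataclass(frozen=True)
class MechanicalState:
    displacement: np.ndarray  # (3, nx, ny, nz), mm
    von_mises_stress: ImageVolume  # kPa


def material_field_from_domain(domain: BreastDomain, config: StudyConfig) -> MaterialField:
    e_by_label = config.young_modulus_by_label()
    e = e_by_label[domain.labels_array]
    return MaterialField(
        young_modulus=domain.mask.with_values(e),
        poisson_ratio=config.nu,
        coupling=config.lam,
    )


def _central_grad(f: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Central difference with zero ghost values outside the grid."""
    g = np.zeros_like(f)
    sl_hi = [slice(None)] * 3
    sl_lo = [slice(None)] * 3
    sl_mid = [slice(None)] * 3
    sl_hi[axis] = slice(2, None)
    sl_lo[axis] = slice(None, -2)
    sl_mid[axis] = slice(1, -1)
    g[tuple(sl_mid)] = (f[tuple(sl_hi)] - f[tuple(sl_lo)]) / (2.0 * h)
    # one-sided ghosts: values outside the array are zero
    first = [slice(None)] * 3
    second = [slice(None)] * 3
    first[axis] = 0
    second[axis] = 1
    g[tuple(first)] = f[tuple(second)] / (2.0 * h)
    last = [slice(None)] * 3
    penult = [slice(None)] * 3
    last[axis] = -1
    penult[axis] = -2
    g[tuple(last)] = -f[tuple(penult)] / (2.0 * h)
    return g


def _grad_matrix(shape: tuple, axis: int, h: float) -> sparse.csr_matrix:
    """Sparse central-difference gradient on the flattened grid (zero ghosts)."""
    n = int(np.prod(shape))
    coords = np.indices(shape).reshape(3, n)
    stride = int(np.prod(shape[axis + 1 :]))
    i = np.arange(n)
    has_hi = coords[axis] < shape[axis] - 1
    has_lo = coords[axis] > 0
    rows = np.concatenate([i[has_hi], i[has_lo]])
    cols = np.concatenate([i[has_hi] + stride, i[has_lo] - stride])
    data = np.concatenate(
        [np.full(has_hi.sum(), 1.0 / (2 * h)), np.full(has_lo.sum(), -1.0 / (2 * h))]
    )
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def _fluxdiv_matrix(shape: tuple, axis: int, h: float, g: np.ndarray) -> sparse.csr_matrix:
    """Sparse d/dx(G d/dx) with face-averaged G and zero Dirichlet ghosts."""
    n = int(np.prod(shape))
    coords = np.indices(shape).reshape(3, n)
    stride = int(np.prod(shape[axis + 1 :]))
    gf = g.ravel()
    i = np.arange(n)
    has_hi = coords[axis] < shape[axis] - 1
    has_lo = coords[axis] > 0
    g_hi = np.where(has_hi, 0.5 * (gf + np.roll(gf, -stride)), gf)
    g_lo = np.where(has_lo, 0.5 * (gf + np.roll(gf, stride)), gf)
    rows = np.concatenate([i, i[has_hi], i[has_lo]])
    cols = np.concatenate([i, i[has_hi] + stride, i[has_lo] - stride])
    data = np.concatenate(
        [-(g_hi + g_lo) / h**2, g_hi[has_hi] / h**2, g_lo[has_lo] / h**2]
    )
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


class EquilibriumSolver:
    """Pre-factorized elastic-equilibrium solver for one domain/material pair.

    The discrete operator depends only on the shear-modulus field, the mask,
    and the grid, so it is assembled and LU-factorized once; each call then
    reduces to forming the cell-gradient load and a pair of triangular
    solves.  Displacement is pinned to zero outside the breast mask (rigid
    surroundings), which realizes the zero-displacement condition at the
    mask surface through the dropped columns.
    """

    def __init__(self, materials: MaterialField, domain: BreastDomain):
        mask = domain.mask_array
        self.shape = mask.shape
        self.h = domain.mask.spacing
        self.g3 = materials.shear_modulus
        self.nu = materials.poisson_ratio
        self.lam = materials.coupling
        # skip derivative terms along singleton axes (quasi-1D/2D problems)
        self.active = [d for d in range(3) if self.shape[d] > 1]
        self.mask_flat = mask.ravel()
        self.idx = np.where(self.mask_flat)[0]
        if self.idx.size == 0:
            raise ValueError("empty breast mask")

        gp = self.g3 / (1.0 - 2.0 * self.nu)
        gp_diag = sparse.diags(gp.ravel())
        shape, h = self.shape, self.h
        grads = {d: _grad_matrix(shape, d, h[d]) for d in self.active}
        lap_g = sum(_fluxdiv_matrix(shape, d, h[d], self.g3) for d in self.active)
        blocks = [[None] * 3 for _ in range(3)]
        for c in range(3):
            diag = lap_g.copy()
            if c in self.active:
                diag = diag + _fluxdiv_matrix(shape, c, h[c], gp)
            blocks[c][c] = diag
            for d in self.active:
                if d != c and c in self.active:
                    blocks[c][d] = grads[c] @ gp_diag @ grads[d]
        a_full = sparse.bmat(
            [[b if b is not None else sparse.csr_matrix(diag.shape) for b in row]
             for row in blocks],
            format="csr",
        )
        # restrict rows (equations) and columns (unknowns) to in-mask voxels
        dof = np.concatenate([self.idx + c * self.mask_flat.size for c in range(3)])
        self.dof = dof
        a = a_full[dof][:, dof].tocsc()
        self._a = a
        self._last_x: np.ndarray | None = None
        # exact LU is fast for small systems; large ones use ILU-preconditioned
        # lgmres warm-started from the previous solve
        if a.shape[0] <= 8000:
            self._lu = splu(a)
            self._ilu = None
        else:
            self._lu = None
            self._ilu = spilu(a, drop_tol=1e-4, fill_factor=15)

    def _solve_system(self, b: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
        if self._lu is not None:
            return self._lu.solve(b)
        m = LinearOperator(self._a.shape, self._ilu.solve)
        x, info = lgmres(
            self._a, b, M=m, x0=self._last_x, rtol=rtol, atol=0.0, maxiter=2000
        )
        if info != 0:
            raise RuntimeError(f"elastic equilibrium solver failed to converge (info={info})")
        self._last_x = x
        return x

    def solve(self, n_tc: CellularityMap) -> MechanicalState:
        shape, h = self.shape, self.h
        if n_tc.counts.shape != shape or any(
            abs(a - b) > 1e-6 for a, b in zip(n_tc.counts.spacing, h)
        ):
            raise ValueError("cellularity map is not grid-compatible with the domain")
        n_field = n_tc.counts.values
        rhs = np.zeros((3, *shape))
        for d in self.active:
            rhs[d] = self.lam * _central_grad(n_field, d, h[d])
        b = rhs.reshape(3, -1)[:, self.idx].ravel()
        if not b.any():
            u = np.zeros((3, *shape))
            return MechanicalState(
                displacement=u,
                von_mises_stress=n_tc.counts.with_values(np.zeros(shape)),
            )
        x = self._solve_system(b)
        u = np.zeros((3, *shape))
        m = self.idx.size
        for c in range(3):
            comp = np.zeros(self.mask_flat.size)
            comp[self.idx] = x[c * m : (c + 1) * m]
            u[c] = comp.reshape(shape)
        sigma_vm = _von_mises_from_displacement(u, self.g3, self.nu, h, self.active)
        return MechanicalState(
            displacement=u,
            von_mises_stress=n_tc.counts.with_values(sigma_vm),
        )


def solve_equilibrium(
    n_tc: CellularityMap,
    materials: MaterialField,
    domain: BreastDomain,
    solver: EquilibriumSolver | None = None,
) -> MechanicalState:
    """Solve the cell-gradient-driven elastic equilibrium on the breast domain.

    Pass a cached :class:`EquilibriumSolver` to amortize the factorization
    across repeated solves on the same domain.
    """
    if solver is None:
        solver = EquilibriumSolver(materials, domain)
    return solver.solve(n_tc)


def _von_mises_from_displacement(
    u: np.ndarray, g3: np.ndarray, nu: float, h: tuple, active: list[int]
) -> np.ndarray:
    shape = u.shape[1:]
    grad = np.zeros((3, 3, *shape))
    for c in range(3):
        for d in active:
            grad[c, d] = _central_grad(u[c], d, h[d])
    eps = 0.5 * (grad + grad.transpose(1, 0, 2, 3, 4))
    tr = eps[0, 0] + eps[1, 1] + eps[2, 2]
    lame = 2.0 * g3 * nu / (1.0 - 2.0 * nu)
    sigma = 2.0 * g3 * eps
    for c in range(3):
        sigma[c, c] += lame * tr
    return von_mises_array(sigma)


def von_mises_array(sigma: np.ndarray) -> np.ndarray:
    """Von Mises invariant of a symmetric stress field shaped (3, 3, ...)."""
    s11, s22, s33 = sigma[0, 0], sigma[1, 1], sigma[2, 2]
    s12, s23, s31 = sigma[0, 1], sigma[1, 2], sigma[2, 0]
    return np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * (s12**2 + s23**2 + s31**2)
    )


def von_mises(stress_tensor_field: np.ndarray) -> np.ndarray:
    """Von Mises stress (kPa) from a symmetric 3x3-per-voxel tensor field."""
    sigma = np.asarray(stress_tensor_field, dtype=np.float64)
    if sigma.shape[:2] != (3, 3):
        raise ValueError("expected leading shape (3, 3)")
    if not np.allclose(sigma, sigma.transpose(1, 0, *range(2, sigma.ndim))):
        raise ValueError("stress tensor field must be symmetric")
    return von_mises_array(sigma)


def damp_diffusion(d0: float, sigma_vm: ImageVolume, gamma: float) -> ImageVolume:
    """D = D0 exp(-gamma sigma_vm); monotone in stress, bounded by D0."""
    if d0 < 0 or gamma < 0:
        raise ValueError("d0 and gamma must be nonnegative")
    return sigma_vm.with_values(d0 * np.exp(-gamma * sigma_vm.values))
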