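"""Model calibration on two imaging time points.

Globals {D0, alpha1, alpha2, beta1, beta2, mu} and the voxelwise
proliferation map k(x) are fitted by Levenberg-Marquardt-type least
squares against the scan-2 cellularity map, simulating forward from the
scan-1 map on a block-down-sampled grid (factor 4 in the reference
protocol; cell counts down-sampled in sum mode with theta rescaled so
N / theta is preserved).

The fit alternates two stages: (A) globals with k fixed, (B) voxelwise k
with globals fixed, where k is initialized from a closed-form logistic
inversion of the per-voxel change between scans.  An optional smoothness
penalty on k (weighted discrete Laplacian residuals) regularizes the
otherwise under-determined voxelwise stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .grid import (
    LABEL_ADIPOSE,
    BreastDomain,
    ImageVolume,
    StudyConfig,
    TreatmentSchedule,
    downsample_by_factor,
)
from .model import ModelParameters, ModelVariant, simulate
from .quantities import CellularityMap, DrugFieldSet

__all__ = [
    "CalibrationProblem",
    "CalibrationResult",
    "default_bounds",
    "downsample_problem",
    "objective_sse",
    "calibrate",
]

log = logging.getLogger(__name__)

GLOBAL_NAMES = ("d0", "alpha1", "alpha2", "beta1", "beta2", "mu")

_PENALTY = 1e12  # SSE surrogate returned on simulation blow-up


@dataclass
class CalibrationProblem:
    """Down-sampled two-scan fitting problem."""

    scan1: CellularityMap
    scan2: CellularityMap
    drug_fields: DrugFieldSet
    domain: BreastDomain
    schedule: TreatmentSchedule
    bounds: dict[str, tuple[float, float]]
    config: StudyConfig = field(default_factory=StudyConfig)
    initial_guess: dict[str, float] = field(
        default_factory=lambda: {
            "d0": 1e-3, "alpha1": 0.1, "alpha2": 0.1, "mu": 0.1
        }
    )
    k_support_dilation: int = 2
    k_smoothness_weight: float = 0.0
    mechanics_cadence: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("beta1", "beta2"):
            lo, hi = self.bounds[name]
            if lo <= 0:
                raise ValueError(f"{name} lower bound must be strictly positive")
        union = self.scan1.roi | self.scan2.roi
        if not union.any():
            raise ValueError("union tumor ROI is empty")

    @property
    def union_roi(self) -> np.ndarray:
        return self.scan1.roi | self.scan2.roi

    @property
    def k_support(self) -> np.ndarray:
        support = ndimage.binary_dilation(
            self.union_roi, iterations=self.k_support_dilation
        )
        return support & self.domain.mask_array


@dataclass
class CalibrationResult:
    params: ModelParameters
    sse: float
    n_iterations: int
    converged: bool
    residual_map: ImageVolume
    variant: ModelVariant = "pet_mri"

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be nonnegative")


def default_bounds(config: StudyConfig, spacing: tuple[float, float, float]) -> dict:
    """Parameter box from configured half-life ranges, CFL cap, and caps.

    beta bounds are ln2 / t_half with the half-life range flipped;
    D0 is capped by the explicit-scheme CFL limit at dt.
    """
    hl = config.chemo_half_life_days
    if "drug1" not in hl or "drug2" not in hl:
        raise ValueError("chemo_half_life_days must define 'drug1' and 'drug2' ranges")
    bounds: dict[str, tuple[float, float]] = {}
    for name, key in (("beta1", "drug1"), ("beta2", "drug2")):
        t_min, t_max = hl[key]
        if t_min > t_max or t_min <= 0:
            raise ValueError(f"invalid half-life range for {key}: ({t_min}, {t_max})")
        bounds[name] = (np.log(2) / t_max, np.log(2) / t_min)
    d_cap = 1.0 / (2.0 * config.dt * sum(1.0 / h**2 for h in spacing))
    bounds["d0"] = (0.0, d_cap)
    bounds["alpha1"] = (0.0, config.alpha_cap)
    bounds["alpha2"] = (0.0, config.alpha_cap)
    bounds["mu"] = (0.0, 1.0)
    bounds["k"] = (-config.k_cap, config.k_cap)
    return bounds


# ---------------------------------------------------------------------------
# Problem construction


def _downsample_domain(domain: BreastDomain, factor: int) -> BreastDomain:
    mask_c = downsample_by_factor(domain.mask, factor, mode="mean")
    labels = domain.labels_array
    # majority label among in-mask fine voxels per block
    fracs = [
        downsample_by_factor(
            domain.mask.with_values((labels == lab).astype(float)), factor, mode="mean"
        ).values
        for lab in (1, 2, 3)
    ]
    frac = np.stack(fracs)
    mask_arr = mask_c.values >= 0.5
    lab_c = np.where(mask_arr, np.argmax(frac, axis=0) + 1, 0)
    # blocks that are majority-breast but had no labeled fine voxel cannot
    # occur (label fraction >= mask fraction), but guard anyway
    lab_c[mask_arr & (frac.max(axis=0) == 0)] = LABEL_ADIPOSE
    return BreastDomain(
        mask=mask_c.with_values(mask_arr.astype(float)),
        tissue_labels=mask_c.with_values(lab_c.astype(float)),
    )


def downsample_problem(
    scan1: CellularityMap,
    scan2: CellularityMap,
    drug_fields: DrugFieldSet,
    domain: BreastDomain,
    factor: int,
    **kwargs,
) -> CalibrationProblem:
    """Block down-sample all fields by ``factor`` and build the problem.

    Cell counts use sum mode with theta scaled by ``factor**3``; drug maps
    and the mask use mean mode.
    """
    theta_c = scan1.theta * factor**3
    dom_c = _downsample_domain(domain, factor)

    def cells(m: CellularityMap) -> CellularityMap:
        counts = downsample_by_factor(m.counts, factor, mode="sum")
        roi = counts.values > 0
        return CellularityMap(counts, theta_c, roi)

    def intensity(v: ImageVolume) -> ImageVolume:
        out = downsample_by_factor(v, factor, mode="mean")
        return out.with_values(np.clip(out.values, 0.0, 1.0))

    drugs_c = DrugFieldSet(
        intensity(drug_fields.chemo_map_scan1),
        intensity(drug_fields.chemo_map_scan2),
        intensity(drug_fields.trastuzumab_map),
        drug_fields.schedule,
    )
    scan1_c, scan2_c = cells(scan1), cells(scan2)
    config = kwargs.pop("config", StudyConfig())
    bounds = kwargs.pop("bounds", None)
    if bounds is None:
        bounds = default_bounds(config, scan1_c.counts.spacing)
    return CalibrationProblem(
        scan1=scan1_c,
        scan2=scan2_c,
        drug_fields=drugs_c,
        domain=dom_c,
        schedule=drug_fields.schedule,
        bounds=bounds,
        config=config,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Objective


def _make_params(
    problem: CalibrationProblem, glob: np.ndarray, k_map: np.ndarray
) -> ModelParameters:
    d0, a1, a2, b1, b2, mu = glob
    return ModelParameters(
        d0=d0, k_map=k_map, theta=problem.scan1.theta,
        alpha1=a1, alpha2=a2, beta1=b1, beta2=b2, mu=mu,
        config=problem.config,
    )


def _residuals(
    problem: CalibrationProblem, params: ModelParameters, variant: ModelVariant
) -> np.ndarray:
    """Simulated-minus-measured counts over the union ROI at scan-2 time."""
    support = problem.union_roi
    if getattr(problem, "_mech_solver", None) is None and params.d0 > 0:
        from .mechanics import EquilibriumSolver, material_field_from_domain

        problem._mech_solver = EquilibriumSolver(
            material_field_from_domain(problem.domain, problem.config), problem.domain
        )
    try:
        result = simulate(
            problem.scan1,
            problem.schedule.scan1_time,
            problem.schedule.scan2_time,
            params,
            problem.drug_fields,
            problem.domain,
            model_variant=variant,
            mechanics_cadence=problem.mechanics_cadence,
            mech_solver=getattr(problem, "_mech_solver", None),
        )
    except FloatingPointError:
        log.warning("simulation blow-up during calibration; returning penalty")
        scale = max(problem.scan2.theta, 1.0)
        return np.full(int(support.sum()), np.sqrt(_PENALTY) * scale)
    sim = result.final.counts.values
    meas = problem.scan2.counts.values
    return (sim - meas)[support]


def objective_sse(
    params: ModelParameters,
    problem: CalibrationProblem,
    model_variant: ModelVariant = "pet_mri",
) -> tuple[float, np.ndarray]:
    """Sum of squared simulated-vs-measured count errors and the residuals."""
    r = _residuals(problem, params, model_variant)
    return float(r @ r), r


# ---------------------------------------------------------------------------
# Initialization


def _logistic_k_init(problem: CalibrationProblem) -> np.ndarray:
    """Closed-form per-voxel logistic-rate estimate ignoring diffusion and
    therapy: k = ln[N2 (theta - N1) / (N1 (theta - N2))] / (t2 - t1)."""
    theta = problem.scan1.theta
    n1 = problem.scan1.counts.values
    n2 = problem.scan2.counts.values
    dt = problem.schedule.scan2_time - problem.schedule.scan1_time
    support = problem.k_support
    eps = 1e-6 * theta
    n1c = np.clip(n1, eps, theta - eps)
    n2c = np.clip(n2, eps, theta - eps)
    k = np.log(n2c * (theta - n1c) / (n1c * (theta - n2c))) / dt
    k_lo, k_hi = problem.bounds["k"]
    k = np.clip(k, k_lo, k_hi)
    both = (n1 > 0) & (n2 > 0)
    return np.where(support & both, k, 0.0)


# ---------------------------------------------------------------------------
# Two-stage alternating fit


def _poly_basis(support: np.ndarray, degree: int) -> list[np.ndarray]:
    """Polynomial fields (constant, linear, quadratic diagonal) normalized
    over the k support."""
    coords = np.indices(support.shape).astype(float)
    for d in range(3):
        on = coords[d][support]
        coords[d] = (coords[d] - on.mean()) / max(on.std(), 1e-9)
    basis = [np.ones(support.shape)]
    if degree >= 1:
        basis += [coords[d] for d in range(3)]
    if degree >= 2:
        basis += [coords[d] ** 2 for d in range(3)]
    return basis


def _fit_globals(
    problem: CalibrationProblem,
    glob0: np.ndarray,
    k_map: np.ndarray,
    variant: ModelVariant,
    max_nfev: int,
    joint_k_degree: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Stage A: globals via bounded trust-region least squares.

    On the first outer loop (``joint_k_degree`` given) a low-order
    polynomial proliferation field over the k support is fitted jointly
    with the globals.  This keeps the stage identifiable — a free voxelwise
    k could absorb the therapy terms entirely — while still letting
    large-scale growth heterogeneity separate from the global rates.
    Later loops refit the globals with the voxelwise k frozen.
    """
    free = [n for n in GLOBAL_NAMES if not (variant == "mri" and n == "mu")]
    idx = [GLOBAL_NAMES.index(n) for n in free]
    lo = [problem.bounds[n][0] for n in free]
    hi = [problem.bounds[n][1] for n in free]
    support = problem.k_support
    joint_k = joint_k_degree is not None
    if joint_k:
        basis = _poly_basis(support, joint_k_degree)
        k_lo, k_hi = problem.bounds["k"]
        lo += [k_lo] + [-k_hi] * (len(basis) - 1)
        hi += [k_hi] + [k_hi] * (len(basis) - 1)
    lo, hi = np.array(lo), np.array(hi)
    nglob = len(idx)
    x0 = list(np.clip(glob0[idx], lo[:nglob], hi[:nglob]))
    if joint_k:
        level0 = float(np.median(k_map[support])) if support.any() else 0.02
        x0 += [np.clip(level0, k_lo, k_hi)] + [0.0] * (len(basis) - 1)
    x0 = np.array(x0)

    def build_k(x: np.ndarray) -> np.ndarray:
        if not joint_k:
            return k_map
        field = sum(c * b for c, b in zip(x[nglob:], basis))
        return np.where(support, field, 0.0)

    def fun(x: np.ndarray) -> np.ndarray:
        g = glob0.copy()
        g[idx] = x[:nglob]
        return _residuals(problem, _make_params(problem, g, build_k(x)), variant)

    scale = np.maximum(np.abs(x0), 0.05 * (hi - lo + 1e-12))
    res = least_squares(
        fun, x0, bounds=(lo, hi), method="trf",
        diff_step=1e-4, x_scale=scale, max_nfev=max_nfev,
    )
    out = glob0.copy()
    out[idx] = res.x[:nglob]
    k_fit = build_k(res.x) if joint_k else None
    try:
        jac = np.asarray(res.jac)
        sv = np.linalg.svd(jac, compute_uv=False)
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        log.info("global-stage Jacobian condition number: %.3g", cond)
        corr = np.corrcoef(jac.T)
        for i in range(len(free)):
            for j in range(i + 1, len(free)):
                if abs(corr[i, j]) > 0.95:
                    log.info(
                        "strongly correlated parameter pair: %s vs %s (r=%.3f)",
                        free[i], free[j], corr[i, j],
                    )
    except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
        pass
    return out, k_fit


def _fit_k(
    problem: CalibrationProblem,
    glob: np.ndarray,
    k_map0: np.ndarray,
    variant: ModelVariant,
    max_nfev: int,
) -> np.ndarray:
    support = problem.k_support
    sidx = np.where(support)
    k_lo, k_hi = problem.bounds["k"]
    x0 = np.clip(k_map0[sidx], k_lo, k_hi)
    w = problem.k_smoothness_weight
    theta = problem.scan1.theta

    def assemble(x: np.ndarray) -> np.ndarray:
        k = np.zeros(support.shape)
        k[sidx] = x
        return k

    def fun(x: np.ndarray) -> np.ndarray:
        k = assemble(x)
        r = _residuals(problem, _make_params(problem, glob, k), variant)
        if w > 0:
            lap = ndimage.laplace(k)[sidx]
            r = np.concatenate([r, w * theta * lap])
        return r

    res = least_squares(
        fun, x0, bounds=(k_lo, k_hi), method="trf",
        diff_step=1e-4, x_scale=max(abs(np.median(x0)), 0.01),
        max_nfev=max_nfev,
    )
    return assemble(res.x)


def calibrate(
    problem: CalibrationProblem,
    model_variant: ModelVariant = "pet_mri",
    max_outer: int = 10,
    sse_rtol: float = 1e-3,
    max_nfev_globals: int = 300,
    max_nfev_k: int = 40,
    joint_k_degree: int = 2,
) -> CalibrationResult:
    """Alternating two-stage least-squares fit.

    The first stage A fits the global rates jointly with a low-order
    polynomial proliferation field (see ``_fit_globals``); stage B then
    polishes k voxelwise with the globals frozen.  Later loops alternate
    globals (k frozen) and k (globals frozen).  Alternation stops when the
    SSE improves by less than ``sse_rtol`` relative or after ``max_outer``
    loops.  Deterministic given the problem (finite-difference Jacobians,
    fixed initialization).
    """
    guess = problem.initial_guess
    beta_mid = {
        n: float(np.sqrt(problem.bounds[n][0] * problem.bounds[n][1]))
        for n in ("beta1", "beta2")
    }
    glob = np.array([
        guess.get("d0", 1e-3),
        guess.get("alpha1", 0.1),
        guess.get("alpha2", 0.1),
        guess.get("beta1", beta_mid["beta1"]),
        guess.get("beta2", beta_mid["beta2"]),
        guess.get("mu", 0.1) if model_variant == "pet_mri" else 0.0,
    ])
    # the logistic inversion estimates the *net* per-voxel rate (therapy
    # included), so it only seeds the level of the joint first stage; using
    # it directly as a frozen k would absorb the therapy terms
    k_init = _logistic_k_init(problem)
    k_pos = k_init[problem.k_support & (k_init > 0)]
    level0 = float(np.median(k_pos)) if k_pos.size else 0.02
    k_map = np.where(problem.k_support, guess.get("k_level", level0), 0.0)

    sse, _ = objective_sse(_make_params(problem, glob, k_map), problem, model_variant)
    log.info("calibration start: sse=%.6g", sse)
    history = [sse]
    converged = False
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        glob, k_poly = _fit_globals(
            problem, glob, k_map, model_variant, max_nfev_globals,
            joint_k_degree=joint_k_degree if n_outer == 1 else None,
        )
        if k_poly is not None:
            k_map = k_poly
        k_map = _fit_k(problem, glob, k_map, model_variant, max_nfev_k)
        sse_new, _ = objective_sse(
            _make_params(problem, glob, k_map), problem, model_variant
        )
        if sse_new > sse:  # stages never accept a worse fit individually;
            sse_new = sse  # guard against FD noise in the bookkeeping
        log.info("outer loop %d: sse=%.6g", n_outer, sse_new)
        history.append(sse_new)
        meas2 = float((problem.scan2.counts.values[problem.union_roi] ** 2).sum())
        if sse_new <= 1e-12 * meas2 or (sse > 0 and (sse - sse_new) / sse < sse_rtol):
            converged = True
            sse = sse_new
            break
        sse = sse_new

    params = _make_params(problem, glob, k_map)
    sse, residuals = objective_sse(params, problem, model_variant)
    res_map = np.zeros(problem.union_roi.shape)
    res_map[problem.union_roi] = residuals
    return CalibrationResult(
        params=params,
        sse=sse,
        n_iterations=n_outer,
        converged=converged,
        residual_map=problem.scan1.counts.with_values(res_map),
        variant=model_variant,
    )
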