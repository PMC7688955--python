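"""Forward integration of the mechanically coupled reaction-diffusion model.

State: tumor cells per voxel N(x, t).  Dynamics:

    dN/dt = div(D grad N) + k_H (1 - N / theta) N - C_drug(x, t) N

with D stress-damped (``mechanics``), k_H = k * g where g encodes the
constant post-administration effect of the targeted antibodies
(g = 1 - 2 mu [trastuzumab]), and C_drug the superposition of decaying
per-dose chemotherapy fields.  Explicit forward-Euler stepping with
dt = 0.25 day, 7-point flux-form diffusion stencil with face-averaged D,
and zero flux across the breast-mask boundary.  The "mri" variant forces
the targeted-therapy modulation off; with mu = 0 the two variants
coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .grid import BreastDomain, ImageVolume, StudyConfig
from .mechanics import (
    EquilibriumSolver,
    MaterialField,
    damp_diffusion,
    material_field_from_domain,
)
from .quantities import CellularityMap, DrugFieldSet

__all__ = [
    "ModelParameters",
    "SimulationResult",
    "chemo_field",
    "growth_modulation",
    "step",
    "simulate",
    "check_stability",
]

ModelVariant = Literal["mri", "pet_mri"]


@dataclass
class ModelParameters:
    """Global rates plus the voxelwise proliferation map.

    Rates are per day; ``mu`` is dimensionless.  Fixed mechanical and
    numerical constants live in ``config``.
    """

    d0: float
    k_map: np.ndarray
    theta: float
    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    mu: float
    config: StudyConfig = field(default_factory=StudyConfig)

    def __post_init__(self) -> None:
        if min(self.d0, self.alpha1, self.alpha2, self.beta1, self.beta2, self.mu) < 0:
            raise ValueError("d0, alphas, betas and mu must be nonnegative")
        self.k_map = np.asarray(self.k_map, dtype=np.float64)
        if not np.all(np.isfinite(self.k_map)):
            raise ValueError("k_map must be finite")

    def globals_vector(self) -> np.ndarray:
        return np.array([self.d0, self.alpha1, self.alpha2, self.beta1, self.beta2, self.mu])


@dataclass
class SimulationResult:
    times: np.ndarray               # days
    total_cellularity: np.ndarray   # cells
    volume: np.ndarray              # mm^3
    final: CellularityMap
    snapshots: list[CellularityMap] | None = None
    clip_events: int = 0            # voxels clipped back into [0, theta]


def chemo_field(
    t: float, drug_maps: DrugFieldSet, params: ModelParameters
) -> np.ndarray:
    """Therapy decay field C_drug(x, t) in 1/day.

    Additive superposition over all administered doses: each dose at t_d
    contributes alpha_i * M(x; t_d) * exp(-beta_i (t - t_d)) per drug,
    where M is the scan-1 normalized AUC map for doses given before
    scan 2 and the scan-2 map afterwards.
    """
    shape = drug_maps.chemo_map_scan1.shape
    out = np.zeros(shape)
    for td in drug_maps.schedule.doses_before(t):
        m = drug_maps.chemo_map_at(td).values
        dt = t - td
        out += m * (
            params.alpha1 * np.exp(-params.beta1 * dt)
            + params.alpha2 * np.exp(-params.beta2 * dt)
        )
    return out


def growth_modulation(
    trastuzumab_map: ImageVolume, mu: float, targeted_started: bool
) -> np.ndarray:
    """g = 1 - 2 mu [trastuzumab] once targeted therapy has been given.

    The effect is constant in time after the first administration (no
    antibody clearance); before it, g = 1 everywhere.  g may go negative
    (net proliferative decline) since mu is only bounded above by 1.
    """
    if not targeted_started:
        return np.ones(trastuzumab_map.shape)
    return 1.0 - 2.0 * mu * trastuzumab_map.values


def check_stability(
    d_field: np.ndarray | float, spacing: tuple[float, float, float], dt: float
) -> tuple[bool, float]:
    """Explicit-scheme CFL guard for the diffusion term.

    Returns ``(stable, dt_sub)`` where ``dt_sub`` is the largest uniform
    sub-step that divides ``dt`` evenly and satisfies
    ``dt_sub <= 1 / (2 D_max sum(1/h^2))``.
    """
    d_max = float(np.max(d_field))
    if d_max <= 0:
        return True, dt
    limit = 1.0 / (2.0 * d_max * sum(1.0 / h**2 for h in spacing))
    if dt <= limit:
        return True, dt
    n_sub = int(np.ceil(dt / limit))
    return False, dt / n_sub


def _diffusion_term(
    n: np.ndarray, d_field: np.ndarray, mask: np.ndarray, spacing: tuple
) -> np.ndarray:
    """Flux-form div(D grad N); zero flux across the mask boundary."""
    out = np.zeros_like(n)
    for axis in range(3):
        if n.shape[axis] == 1:
            continue
        h = spacing[axis]
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[axis] = slice(1, None)
        sl_lo[axis] = slice(None, -1)
        sl_hi, sl_lo = tuple(sl_hi), tuple(sl_lo)
        d_face = 0.5 * (d_field[sl_hi] + d_field[sl_lo])
        open_face = mask[sl_hi] & mask[sl_lo]
        flux = np.where(open_face, d_face * (n[sl_hi] - n[sl_lo]) / h, 0.0)
        div = np.zeros_like(n)
        div[sl_lo] += flux / h
        div[sl_hi] -= flux / h
        out += div
    return out


def step(
    state: CellularityMap,
    t: float,
    dt: float,
    params: ModelParameters,
    drug_maps: DrugFieldSet,
    domain: BreastDomain,
    d_field: np.ndarray,
    g_field: np.ndarray,
) -> tuple[CellularityMap, int]:
    """One forward-Euler update; returns the new state and the number of
    voxels clipped back into [0, theta].

    ``d_field`` is the (possibly stress-damped) diffusivity and ``g_field``
    the targeted-therapy growth modulation, both precomputed by the caller
    (``simulate`` refreshes them per its cadence).  Sub-steps internally if
    ``dt`` violates the CFL bound.
    """
    mask = domain.mask_array
    spacing = state.counts.spacing
    _, dt_sub = check_stability(d_field, spacing, dt)
    n_sub = max(1, int(round(dt / dt_sub)))
    dt_sub = dt / n_sub

    n = state.counts.values.copy()
    theta = state.theta
    k_eff = params.k_map * g_field
    clipped = 0
    for i in range(n_sub):
        t_now = t + i * dt_sub
        c = chemo_field(t_now, drug_maps, params)
        with np.errstate(invalid="ignore", over="ignore"):  # guard below
            rate = (
                _diffusion_term(n, d_field, mask, spacing)
                + k_eff * (1.0 - n / theta) * n
                - c * n
            )
            n = n + dt_sub * rate
        if not np.all(np.isfinite(n)):
            raise FloatingPointError(
                f"non-finite cellularity at t={t_now + dt_sub:g} d "
                f"(dt={dt_sub:g}, max|k|={np.abs(k_eff).max():g})"
            )
        over = (n < 0) | (n > theta)
        if over.any():
            clipped += int(np.count_nonzero(over))
            n = np.clip(n, 0.0, theta)
    # diffusion may spread cells beyond the initial ROI: track the support
    return state.with_counts(n, roi=(n > 0) | state.roi), clipped


def simulate(
    initial: CellularityMap,
    t0: float,
    t1: float,
    params: ModelParameters,
    drug_maps: DrugFieldSet,
    domain: BreastDomain,
    model_variant: ModelVariant = "pet_mri",
    record_snapshots: bool = False,
    mechanics_cadence: int | None = None,
    mech_solver: EquilibriumSolver | None = None,
) -> SimulationResult:
    """Integrate the model from ``t0`` to ``t1`` (days).

    The elastic equilibrium (and hence the damped diffusivity) is
    recomputed every ``mechanics_cadence`` steps (default from config)
    through a pre-factorized solver, which may be passed in to amortize
    assembly across repeated simulations on one domain.
    ``model_variant="mri"`` disables the targeted-therapy modulation.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    cfg = params.config
    dt = cfg.dt
    cadence = mechanics_cadence if mechanics_cadence is not None else cfg.mechanics_cadence
    mask = domain.mask_array

    first_dose = min(drug_maps.schedule.dose_times, default=np.inf)
    materials = material_field_from_domain(domain, cfg)

    n_steps = int(round((t1 - t0) / dt))
    if abs(t0 + n_steps * dt - t1) > 1e-9:
        raise ValueError(f"(t1 - t0) must be a multiple of dt={dt}")

    from .quantities import tumor_volume  # local import avoids cycle at module load

    voxvol = initial.counts.voxel_volume
    thr = cfg.volume_threshold_fraction

    state = initial
    times = [t0]
    totals = [state.total]
    volumes = [tumor_volume(state, voxvol, thr)]
    snapshots = [state] if record_snapshots else None
    clip_events = 0

    needs_mechanics = params.d0 > 0 and cfg.gamma > 0 and cfg.lam > 0
    d_field = np.full(mask.shape, params.d0)
    if needs_mechanics and mech_solver is None:
        mech_solver = EquilibriumSolver(materials, domain)

    for i in range(n_steps):
        t = t0 + i * dt
        if needs_mechanics and i % cadence == 0:
            mech = mech_solver.solve(state)
            d_field = damp_diffusion(
                params.d0, mech.von_mises_stress, cfg.gamma
            ).values
        if model_variant == "mri":
            g_field = np.ones(mask.shape)
        else:
            g_field = growth_modulation(
                drug_maps.trastuzumab_map, params.mu, targeted_started=t >= first_dose
            )
        state, nclip = step(state, t, dt, params, drug_maps, domain, d_field, g_field)
        clip_events += nclip
        times.append(t + dt)
        totals.append(state.total)
        volumes.append(tumor_volume(state, voxvol, thr))
        if record_snapshots:
            snapshots.append(state)

    return SimulationResult(
        times=np.asarray(times),
        total_cellularity=np.asarray(totals),
        volume=np.asarray(volumes),
        final=state,
        snapshots=snapshots,
        clip_events=clip_events,
    )
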