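"""Virtual-patient generator.

Builds fully aligned two-visit datasets (DW stacks, CE dynamics, PET
uptake, breast domain, treatment schedule) with known ground truth, so the
entire derivation/calibration/forecast chain is testable without clinical
data.  Scan-2 imaging is produced by running the forward model with the
true parameters and inverting the imaging relations (ADC from cellularity,
CE dynamics from perfusion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm

from .grid import (
    LABEL_ADIPOSE,
    LABEL_FIBROGLANDULAR,
    LABEL_TUMOR,
    BreastDomain,
    ImageVolume,
    StudyConfig,
    TreatmentSchedule,
)
from .model import ModelParameters, simulate
from .quantities import (
    CellularityMap,
    DrugFieldSet,
    carrying_capacity,
    cellularity_from_adc,
    compute_auc_drug_map,
    normalize_pet_map,
)

__all__ = [
    "SyntheticPatientSpec",
    "GroundTruth",
    "PatientDataset",
    "generate_breast_domain",
    "generate_scan1_cellularity",
    "synthesize_dw_signals",
    "synthesize_ce_dynamics",
    "synthesize_pet_uptake",
    "generate_longitudinal_study",
    "reference_patient_pair",
]

DEFAULT_B_VALUES = (0.0, 600.0, 800.0, 1000.0, 1500.0)  # s/mm^2


@dataclass
class SyntheticPatientSpec:
    """Geometry, true parameters, and noise knobs for one virtual patient."""

    shape: tuple[int, int, int] = (24, 24, 24)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    breast_semiaxes_mm: tuple[float, float, float] = (22.0, 22.0, 22.0)
    fibroglandular_scale: float = 0.6   # inner-ellipsoid scale; 0 disables
    tumor_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # vs breast center
    tumor_radius_mm: float = 9.0
    # true model parameters
    d0: float = 1.5e-3                  # mm^2/day
    k_base: float = 0.08                # 1/day
    k_variation: float = 0.3            # relative smooth spatial modulation
    k_smoothness_mm: float = 12.0       # correlation length of the k pattern
    alpha1: float = 0.6                 # 1/day
    alpha2: float = 0.25                # 1/day
    beta1: float = 0.15                 # 1/day
    beta2: float = 0.45                 # 1/day
    mu: float = 0.3                     # dimensionless
    # imaging knobs
    adc_min: float = 0.8e-3             # mm^2/s at full cellularity
    adc_healthy: float = 2.0e-3         # mm^2/s outside the tumor
    s0: float = 1000.0                  # baseline DW signal
    perfusion_background: float = 0.4
    perfusion_smoothness_mm: float = 6.0
    perfusion_gradient: float = 0.5     # lateral vascularity ramp amplitude
    pet_ratio: float = 4.0              # tumor-to-background uptake
    pet_fwhm_mm: float = 5.0
    # optional intratumoral uptake heterogeneity: an off-center hot spot at
    # the full ratio with the rest of the tumor at half contrast
    pet_hotspot_offset_mm: tuple[float, float, float] | None = None
    pet_hotspot_radius_mm: float = 5.0
    noise_sd: float = 0.0               # relative SD on synthesized signals
    # schedule
    dose_interval_days: float = 21.0
    n_cycles: int = 6
    scan2_time: float = 42.0
    surgery_time: float = 120.0
    # numerics for the internal forward runs
    mechanics_cadence: int = 4
    roi_threshold_fraction: float = 0.01
    seed: int = 0
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    config: StudyConfig = field(default_factory=StudyConfig)

    def __post_init__(self) -> None:
        if any(self.tumor_radius_mm <= 2 * s for s in self.spacing):
            raise ValueError("tumor radius must exceed 2 voxels along every axis")
        if min(self.d0, self.k_base, self.alpha1, self.alpha2, self.beta1, self.beta2, self.mu) < 0:
            raise ValueError("true rates must be nonnegative")

    def schedule(self) -> TreatmentSchedule:
        doses = tuple(
            i * self.dose_interval_days
            for i in range(self.n_cycles)
            if i * self.dose_interval_days < self.surgery_time
        )
        return TreatmentSchedule(
            dose_times=doses,
            scan1_time=0.0,
            scan2_time=self.scan2_time,
            surgery_time=self.surgery_time,
        )

    def theta(self) -> float:
        cfg = self.config
        if cfg.theta_override is not None:
            return cfg.theta_override
        voxvol = float(np.prod(self.spacing))
        return carrying_capacity(voxvol, cfg.packing_fraction, cfg.cell_radius_um)

    def rng(self, salt: int) -> np.random.Generator:
        """Deterministic per-operation substream."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


@dataclass
class GroundTruth:
    params: ModelParameters
    cellularity_scan1: CellularityMap
    cellularity_scan2: CellularityMap
    cellularity_surgery: CellularityMap
    drug_fields: DrugFieldSet

    def __post_init__(self) -> None:
        for m in (self.cellularity_scan1, self.cellularity_scan2, self.cellularity_surgery):
            v = m.counts.values
            if v.min() < 0 or v.max() > m.theta * (1 + 1e-9):
                raise ValueError("ground-truth cellularity must lie in [0, theta]")


@dataclass
class PatientDataset:
    """Pre-aligned two-visit imaging study on one common grid."""

    domain: BreastDomain
    schedule: TreatmentSchedule
    b_values: tuple[float, ...]
    dw_scan1: list[ImageVolume]
    dw_scan2: list[ImageVolume]
    ce_scan1: list[ImageVolume]
    ce_scan2: list[ImageVolume]
    pet: ImageVolume
    roi_scan1: np.ndarray
    roi_scan2: np.ndarray
    adc_min_ref: float
    theta: float
    config: StudyConfig


# ---------------------------------------------------------------------------
# Geometry


def _coordinate_grids(spec: SyntheticPatientSpec) -> tuple[np.ndarray, ...]:
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.shape, spec.spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def generate_breast_domain(spec: SyntheticPatientSpec) -> BreastDomain:
    """Ellipsoidal breast with an inner fibroglandular region and a
    spherical tumor label at the specified center."""
    x, y, z = _coordinate_grids(spec)
    a, b, c = spec.breast_semiaxes_mm
    mask = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0

    labels = np.zeros(spec.shape)
    labels[mask] = LABEL_ADIPOSE
    f = spec.fibroglandular_scale
    if f > 0:
        fib = (x / (f * a)) ** 2 + (y / (f * b)) ** 2 + (z / (f * c)) ** 2 <= 1.0
        labels[mask & fib] = LABEL_FIBROGLANDULAR

    cx, cy, cz = spec.tumor_center_mm
    r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
    tumor = r2 <= spec.tumor_radius_mm**2
    if not np.all(mask[tumor]):
        raise ValueError("tumor sphere extends outside the breast mask")
    labels[tumor] = LABEL_TUMOR

    ref = ImageVolume(np.zeros(spec.shape), spec.spacing)
    return BreastDomain(
        mask=ref.with_values(mask.astype(np.float64)),
        tissue_labels=ref.with_values(labels),
    )


# ---------------------------------------------------------------------------
# Per-modality synthesizers


def generate_scan1_cellularity(
    spec: SyntheticPatientSpec, domain: BreastDomain
) -> CellularityMap:
    """Per-tumor-voxel counts from a normal distribution truncated to
    [0, theta] (mean theta/2, SD theta/4); zero elsewhere."""
    tumor = domain.tumor_mask
    if not tumor.any():
        raise ValueError("tumor label region is empty")
    theta = spec.theta()
    mean, sd = theta / 2.0, theta / 4.0
    a, b = (0.0 - mean) / sd, (theta - mean) / sd
    rng = spec.rng(1)
    draws = truncnorm.rvs(a, b, loc=mean, scale=sd, size=int(tumor.sum()), random_state=rng)
    counts = np.zeros(spec.shape)
    counts[tumor] = draws
    vol = domain.mask.with_values(counts)
    return CellularityMap(vol, theta, tumor)


def synthesize_dw_signals(
    adc_field: ImageVolume,
    b_values: Sequence[float],
    s0: ImageVolume,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[ImageVolume]:
    """Mono-exponential DW signals S(b) = S0 exp(-b ADC) plus optional
    zero-mean Gaussian noise of SD ``noise_sd * S0``."""
    b = np.asarray(b_values, dtype=np.float64)
    if np.any(b < 0):
        raise ValueError("b-values must be nonnegative")
    if 0.0 not in b:
        raise ValueError("b-values must include 0")
    if np.any(adc_field.values < 0):
        raise ValueError("adc_field must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(0)
    out = []
    for bi in b:
        signal = s0.values * np.exp(-bi * adc_field.values)
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd * s0.values)
        out.append(adc_field.with_values(signal))
    return out


def synthesize_ce_dynamics(
    perfusion_field: ImageVolume,
    n_post: int,
    domain: BreastDomain,
    baseline: float = 100.0,
    amplitude: float = 900.0,
    frame_interval_s: float = 180.0,
    tau_s: float = 180.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[ImageVolume]:
    """Baseline plus ``n_post`` post-contrast frames whose enhancement is
    proportional to perfusion with a saturating profile
    E(t) = A * P * (1 - exp(-t / tau)).

    The baseline frame carries tissue contrast (fibroglandular brighter
    than adipose on this fat-suppressed-like weighting) so tissue
    segmentation has signal to work with."""
    if n_post < 1:
        raise ValueError("need at least one post-contrast frame")
    if rng is None:
        rng = np.random.default_rng(0)
    p = perfusion_field.values
    mask = domain.mask_array
    labels = domain.labels_array
    contrast = np.choose(labels, [0.1, 1.0, 1.5, 1.3])
    frames = [baseline * contrast]
    for j in range(1, n_post + 1):
        t = j * frame_interval_s
        enh = amplitude * p * (1.0 - np.exp(-t / tau_s))
        frames.append(frames[0] + np.where(mask, enh, 0.0))
    if noise_sd > 0:
        frames = [f + rng.normal(0.0, noise_sd * baseline, f.shape) for f in frames]
    return [perfusion_field.with_values(f) for f in frames]


def synthesize_pet_uptake(
    domain: BreastDomain,
    tumor_to_background_ratio: float,
    blur_fwhm_mm: float,
    hotspot_offset_mm: tuple[float, float, float] | None = None,
    hotspot_radius_mm: float = 5.0,
) -> ImageVolume:
    """Piecewise-constant uptake (tumor=ratio, breast=1, outside=0) blurred
    by a Gaussian of the stated FWHM (emulates coarse PET resolution).

    ``hotspot_offset_mm`` places an off-center sphere at the full ratio
    with the rest of the tumor at half contrast, mimicking heterogeneous
    antibody distribution.
    """
    if tumor_to_background_ratio < 1:
        raise ValueError("tumor-to-background ratio must be >= 1")
    if blur_fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    mask = domain.mask_array
    uptake = np.where(mask, 1.0, 0.0)
    tumor = domain.tumor_mask
    if hotspot_offset_mm is None:
        uptake[tumor] = tumor_to_background_ratio
    else:
        uptake[tumor] = 1.0 + (tumor_to_background_ratio - 1.0) / 2.0
        shape = mask.shape
        spacing = domain.mask.spacing
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
        ]
        x, y, z = np.meshgrid(*axes, indexing="ij")
        ox, oy, oz = hotspot_offset_mm
        hot = (x - ox) ** 2 + (y - oy) ** 2 + (z - oz) ** 2 <= hotspot_radius_mm**2
        uptake[tumor & hot] = tumor_to_background_ratio
    if blur_fwhm_mm > 0:
        sigma_vox = [
            blur_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / s
            for s in domain.mask.spacing
        ]
        uptake = ndimage.gaussian_filter(uptake, sigma=sigma_vox)
    return domain.mask.with_values(uptake)


# ---------------------------------------------------------------------------
# Full longitudinal study


def _adc_from_cellularity(
    counts: np.ndarray, roi: np.ndarray, spec: SyntheticPatientSpec, domain: BreastDomain
) -> ImageVolume:
    """Invert the linear cellularity relation; healthy/outside tissue gets
    fixed reference ADC values."""
    cfg = spec.config
    theta = spec.theta()
    adc = np.full(spec.shape, cfg.adc_w)
    adc[domain.mask_array] = spec.adc_healthy
    adc_roi = cfg.adc_w - (counts[roi] / theta) * (cfg.adc_w - spec.adc_min)
    adc[roi] = adc_roi
    return domain.mask.with_values(adc)


def _perfusion_field(spec: SyntheticPatientSpec, domain: BreastDomain) -> ImageVolume:
    base = np.where(domain.mask_array, spec.perfusion_background, 0.0)
    base[domain.tumor_mask] = 1.0
    sigma_vox = [spec.perfusion_smoothness_mm / 2.355 / s for s in spec.spacing]
    smooth = ndimage.gaussian_filter(base, sigma=sigma_vox)
    # lateral vascularity ramp decorrelates perfusion from the PET pattern
    if spec.perfusion_gradient > 0:
        nx = spec.shape[0]
        ramp = 1.0 - spec.perfusion_gradient / 2.0 + spec.perfusion_gradient * (
            np.arange(nx) / max(nx - 1, 1)
        )
        smooth = smooth * ramp[:, None, None]
    smooth = np.where(domain.mask_array, smooth, 0.0)
    peak = smooth.max()
    if peak > 0:
        smooth /= peak
    return domain.mask.with_values(smooth)


def _true_k_map(spec: SyntheticPatientSpec, domain: BreastDomain) -> np.ndarray:
    """Smoothly varying proliferation on the tumor neighborhood."""
    support = ndimage.binary_dilation(domain.tumor_mask, iterations=2)
    support &= domain.mask_array
    rng = spec.rng(2)
    noise = rng.standard_normal(spec.shape)
    sigma_vox = [spec.k_smoothness_mm / 2.355 / s for s in spec.spacing]
    noise = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    noise /= max(np.abs(noise).max(), 1e-12)
    k = spec.k_base * (1.0 + spec.k_variation * noise)
    return np.where(support, np.clip(k, 0.0, None), 0.0)


def generate_longitudinal_study(
    spec: SyntheticPatientSpec,
) -> tuple[PatientDataset, GroundTruth]:
    """Generate the full two-visit dataset plus ground truth.

    Scan-1 cellularity is drawn, inverted to ADC/DW signals; the forward
    model run with the true parameters produces scan-2 (and surgery-time)
    truth, and scan-2 imaging is synthesized consistently with it.
    """
    cfg = spec.config
    theta = spec.theta()
    domain = generate_breast_domain(spec)
    schedule = spec.schedule()

    n1 = generate_scan1_cellularity(spec, domain)
    adc1 = _adc_from_cellularity(n1.counts.values, n1.roi, spec, domain)
    s0_vol = domain.mask.with_values(np.full(spec.shape, spec.s0))
    dw1 = synthesize_dw_signals(adc1, spec.b_values, s0_vol, spec.noise_sd, spec.rng(3))

    perfusion = _perfusion_field(spec, domain)
    ce1 = synthesize_ce_dynamics(
        perfusion, 3, domain, noise_sd=spec.noise_sd, rng=spec.rng(4)
    )
    pet = synthesize_pet_uptake(
        domain, spec.pet_ratio, spec.pet_fwhm_mm,
        hotspot_offset_mm=spec.pet_hotspot_offset_mm,
        hotspot_radius_mm=spec.pet_hotspot_radius_mm,
    )

    chemo_map1 = compute_auc_drug_map(
        ce1, baseline_index=0, roi=domain.mask_array,
        frame_interval_s=cfg.ce_frame_interval_s, breast_mask=domain.mask_array,
    )
    trast_map = normalize_pet_map(pet, roi=domain.mask_array, breast_mask=domain.mask_array)

    params = ModelParameters(
        d0=spec.d0,
        k_map=_true_k_map(spec, domain),
        theta=theta,
        alpha1=spec.alpha1,
        alpha2=spec.alpha2,
        beta1=spec.beta1,
        beta2=spec.beta2,
        mu=spec.mu,
        config=cfg,
    )

    # doses before scan 2 only see the scan-1 map, so a placeholder scan-2
    # map is fine for the first leg
    drug_fields = DrugFieldSet(chemo_map1, chemo_map1, trast_map, schedule)
    leg1 = simulate(
        n1, 0.0, schedule.scan2_time, params, drug_fields, domain,
        model_variant="pet_mri", mechanics_cadence=spec.mechanics_cadence,
    )
    n2 = leg1.final
    roi2 = n2.counts.values >= spec.roi_threshold_fraction * theta
    n2_meas = n2.with_counts(np.where(roi2, n2.counts.values, 0.0), roi2)

    adc2 = _adc_from_cellularity(n2_meas.counts.values, roi2, spec, domain)
    dw2 = synthesize_dw_signals(adc2, spec.b_values, s0_vol, spec.noise_sd, spec.rng(5))
    ce2 = synthesize_ce_dynamics(
        perfusion, 3, domain, noise_sd=spec.noise_sd, rng=spec.rng(6)
    )
    chemo_map2 = compute_auc_drug_map(
        ce2, baseline_index=0, roi=domain.mask_array,
        frame_interval_s=cfg.ce_frame_interval_s, breast_mask=domain.mask_array,
    )
    drug_fields = DrugFieldSet(chemo_map1, chemo_map2, trast_map, schedule)

    leg2 = simulate(
        n2, schedule.scan2_time, schedule.surgery_time, params, drug_fields, domain,
        model_variant="pet_mri", mechanics_cadence=spec.mechanics_cadence,
    )

    dataset = PatientDataset(
        domain=domain,
        schedule=schedule,
        b_values=spec.b_values,
        dw_scan1=dw1,
        dw_scan2=dw2,
        ce_scan1=ce1,
        ce_scan2=ce2,
        pet=pet,
        roi_scan1=n1.roi,
        roi_scan2=roi2,
        adc_min_ref=spec.adc_min,
        theta=theta,
        config=cfg,
    )
    truth = GroundTruth(
        params=params,
        cellularity_scan1=n1,
        cellularity_scan2=n2_meas,
        cellularity_surgery=leg2.final,
        drug_fields=drug_fields,
    )
    return dataset, truth


def make_recovery_twin(
    spec: SyntheticPatientSpec,
    factor: int = 4,
    measurement_noise_sd: float = 0.0,
    k_seed: int = 3,
    study: tuple[PatientDataset, GroundTruth] | None = None,
    **problem_kwargs,
):
    """Parameter-recovery twin at calibration resolution.

    Generates the full fine-grid study, block-down-samples it by
    ``factor``, then replaces scan 2 with a forward run of the model *on
    the down-sampled grid* using a coarse-native smooth truth k — so the
    calibration model class contains the truth exactly and residuals
    vanish at the true parameters.  Optional relative Gaussian measurement
    noise perturbs both cellularity maps.

    Returns ``(problem, true_params, true_k_map)``.
    """
    from scipy import ndimage as _ndi

    from .calibrate import downsample_problem

    dataset, truth = study if study is not None else generate_longitudinal_study(spec)
    problem = downsample_problem(
        truth.cellularity_scan1,
        truth.cellularity_scan2,
        truth.drug_fields,
        dataset.domain,
        factor,
        config=spec.config,
        **problem_kwargs,
    )
    support = (
        _ndi.binary_dilation(problem.scan1.roi, iterations=problem.k_support_dilation)
        & problem.domain.mask_array
    )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17, k_seed]))
    pattern = _ndi.gaussian_filter(rng.standard_normal(support.shape), sigma=2.0)
    pattern /= max(np.abs(pattern).max(), 1e-12)
    k_true = np.where(support, spec.k_base * (1.0 + spec.k_variation * pattern), 0.0)

    true_params = ModelParameters(
        d0=spec.d0, k_map=k_true, theta=problem.scan1.theta,
        alpha1=spec.alpha1, alpha2=spec.alpha2,
        beta1=spec.beta1, beta2=spec.beta2, mu=spec.mu,
        config=spec.config,
    )
    leg = simulate(
        problem.scan1,
        problem.schedule.scan1_time,
        problem.schedule.scan2_time,
        true_params,
        problem.drug_fields,
        problem.domain,
        model_variant="pet_mri",
        mechanics_cadence=problem.mechanics_cadence,
    )
    problem.scan2 = leg.final

    if measurement_noise_sd > 0:
        theta = problem.scan1.theta
        for attr in ("scan1", "scan2"):
            m: CellularityMap = getattr(problem, attr)
            noisy = m.counts.values * (
                1.0 + measurement_noise_sd * rng.standard_normal(m.counts.shape)
            )
            noisy = np.where(m.roi, np.clip(noisy, 0.0, theta), 0.0)
            setattr(problem, attr, CellularityMap(m.counts.with_values(noisy), theta, m.roi))
    return problem, true_params, k_true


def reference_patient_pair(seed: int = 11) -> tuple[SyntheticPatientSpec, SyntheticPatientSpec]:
    """The packaged pCR-like / non-pCR-like virtual pair.

    The first patient responds: high, fairly uniform antibody uptake and a
    strong targeted effect drive net cell decline after scan 2.  The
    second does not: weak uptake and targeted effect let proliferation
    dominate between doses.  Both receive four every-3-week cycles with
    the midpoint scan after two, and surgery 73 days after scan 2.
    """
    cfg = StudyConfig(
        chemo_half_life_days={"drug1": (4.0, 12.0), "drug2": (1.0, 3.0)},
        volume_threshold_fraction=0.01,
    )
    common = dict(
        shape=(20, 20, 20),
        spacing=(2.0, 2.0, 2.0),
        breast_semiaxes_mm=(17.0, 17.0, 17.0),
        tumor_radius_mm=7.0,
        d0=0.1,
        alpha1=0.2,
        alpha2=0.08,
        beta1=0.1,
        beta2=0.3,
        k_variation=0.3,
        scan2_time=42.0,
        surgery_time=115.0,
        n_cycles=4,
        mechanics_cadence=8,
    )
    pcr = SyntheticPatientSpec(
        seed=seed, mu=0.6, pet_ratio=6.0, pet_fwhm_mm=4.0, k_base=0.15,
        config=cfg, **common,
    )
    non_pcr = SyntheticPatientSpec(
        seed=seed + 1, mu=0.1, pet_ratio=2.0, pet_fwhm_mm=8.0, k_base=0.12,
        config=cfg, **common,
    )
    return pcr, non_pcr
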