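"""Derivation of modeling quantities from the imaging volumes.

Covers ADC map fitting, tumor-ROI segmentation (fuzzy c-means on the
enhancement feature), adipose/fibroglandular tissue labeling (k-means),
normalized drug-distribution maps, the ADC-to-cellularity conversion, the
carrying capacity, and the tumor-volume metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .grid import (
    LABEL_ADIPOSE,
    LABEL_FIBROGLANDULAR,
    LABEL_TUMOR,
    BreastDomain,
    ImageVolume,
    TreatmentSchedule,
)

__all__ = [
    "CellularityMap",
    "DrugFieldSet",
    "fit_adc",
    "segment_tumor_fcm",
    "segment_tissues_kmeans",
    "compute_auc_drug_map",
    "normalize_pet_map",
    "carrying_capacity",
    "cellularity_from_adc",
    "tumor_volume",
]


@dataclass(frozen=True)
class CellularityMap:
    """Tumor cells per voxel with carrying capacity ``theta`` and tumor ROI."""

    counts: ImageVolume
    theta: float
    roi: np.ndarray

    def __post_init__(self) -> None:
        roi = np.asarray(self.roi, dtype=bool)
        if roi.shape != self.counts.shape:
            raise ValueError("roi shape must match counts shape")
        c = self.counts.values
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if np.any(c < 0) or np.any(c > self.theta * (1 + 1e-9)):
            raise ValueError("counts must lie in [0, theta]")
        if np.any(c[~roi] != 0):
            raise ValueError("counts must be zero outside the ROI")
        object.__setattr__(self, "roi", roi)

    @property
    def total(self) -> float:
        return float(self.counts.values.sum())

    def with_counts(self, counts: np.ndarray, roi: np.ndarray | None = None) -> "CellularityMap":
        return CellularityMap(
            self.counts.with_values(counts),
            self.theta,
            self.roi if roi is None else roi,
        )


@dataclass(frozen=True)
class DrugFieldSet:
    """Normalized spatial drug-distribution maps plus the dose schedule.

    ``chemo_map_scan1``/``chemo_map_scan2`` are the normalized CE-AUC maps
    used for doses given before/after scan 2; ``trastuzumab_map`` is the
    normalized PET-uptake map.  All maps are dimensionless in [0, 1].
    """

    chemo_map_scan1: ImageVolume
    chemo_map_scan2: ImageVolume
    trastuzumab_map: ImageVolume
    schedule: TreatmentSchedule

    def __post_init__(self) -> None:
        for name in ("chemo_map_scan1", "chemo_map_scan2", "trastuzumab_map"):
            v = getattr(self, name).values
            if v.min() < 0 or v.max() > 1 + 1e-12:
                raise ValueError(f"{name} must lie in [0, 1]")

    def chemo_map_at(self, dose_time: float) -> ImageVolume:
        """Spatial chemo map in effect for a dose given at ``dose_time``."""
        if dose_time < self.schedule.scan2_time:
            return self.chemo_map_scan1
        return self.chemo_map_scan2


# ---------------------------------------------------------------------------
# ADC


def fit_adc(
    dw_stack: Sequence[ImageVolume],
    b_values: Sequence[float],
    adc_w: float = 3.0e-3,
) -> ImageVolume:
    """Voxelwise ADC (mm^2/s) from a multi-b-value DW stack.

    Ordinary least squares of ``ln S(b)`` against ``b``; ADC is minus the
    slope.  Voxels with any nonpositive signal are treated as fluid or
    background and assigned ``adc_w``; negative fitted slopes are floored
    at zero.
    """
    b = np.asarray(b_values, dtype=np.float64)
    if len(dw_stack) != b.size:
        raise ValueError("need one volume per b-value")
    if np.unique(b).size < 2:
        raise ValueError("need at least 2 distinct b-values")
    signals = np.stack([v.values for v in dw_stack], axis=-1)
    valid = np.all(signals > 0, axis=-1)
    logs = np.where(signals > 0, np.log(np.where(signals > 0, signals, 1.0)), 0.0)
    # OLS slope of log-signal vs b, vectorized over voxels
    bc = b - b.mean()
    denom = float((bc**2).sum())
    slope = (logs * bc).sum(axis=-1) / denom
    adc = np.clip(-slope, 0.0, None)
    adc[~valid] = adc_w
    return dw_stack[0].with_values(adc)


# ---------------------------------------------------------------------------
# Fuzzy c-means tumor ROI

_FCM_M = 2.0  # fuzzifier
_FCM_TOL = 1e-5
_FCM_MAX_ITER = 300


def _fcm_1d(feature: np.ndarray, n_classes: int, rng: np.random.Generator):
    """Fuzzy c-means on a 1D feature; returns (memberships, centers)."""
    x = feature.astype(np.float64)
    n = x.size
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        raise ValueError("degenerate feature: all values identical")
    # deterministic spread of initial centers across the data range
    centers = lo + (np.arange(n_classes) + 0.5) / n_classes * (hi - lo)
    u = np.full((n, n_classes), 1.0 / n_classes)
    power = 2.0 / (_FCM_M - 1.0)
    for _ in range(_FCM_MAX_ITER):
        d2 = (x[:, None] - centers[None, :]) ** 2
        d2 = np.maximum(d2, 1e-30)
        inv = d2 ** (-1.0 / power)
        u_new = inv / inv.sum(axis=1, keepdims=True)
        w = u_new**_FCM_M
        centers = (w * x[:, None]).sum(axis=0) / w.sum(axis=0)
        if np.abs(u_new - u).max() < _FCM_TOL:
            u = u_new
            break
        u = u_new
    return u, centers


def segment_tumor_fcm(
    ce_stack: Sequence[ImageVolume],
    conservative_roi: np.ndarray,
    n_classes: int = 2,
    membership_threshold: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Tumor mask from fuzzy c-means clustering of the enhancement feature.

    The feature is late post-contrast signal minus baseline, restricted to
    a conservative hand-drawn ROI.  The class with the highest center is
    tumor; voxels whose tumor-class membership meets the threshold are
    returned.
    """
    roi = np.asarray(conservative_roi, dtype=bool)
    if not roi.any():
        raise ValueError("conservative ROI is empty")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if rng is None:
        rng = np.random.default_rng(0)
    enhancement = ce_stack[-1].values - ce_stack[0].values
    feature = enhancement[roi]
    u, centers = _fcm_1d(feature, n_classes, rng)
    tumor_class = int(np.argmax(centers))
    mask = np.zeros(roi.shape, dtype=bool)
    mask[roi] = u[:, tumor_class] >= membership_threshold
    return mask


# ---------------------------------------------------------------------------
# Tissue segmentation


def segment_tissues_kmeans(
    ce_baseline: ImageVolume,
    mask: np.ndarray,
    tumor_roi: np.ndarray,
    adipose_is_lower_intensity: bool = True,
    seed: int = 0,
) -> BreastDomain:
    """Label adipose vs fibroglandular tissue by 2-means on baseline intensity.

    Tumor-ROI voxels are labeled tumor and excluded from the clustering.
    Which cluster is adipose follows the contrast convention flag.
    """
    mask = np.asarray(mask, dtype=bool)
    tumor_roi = np.asarray(tumor_roi, dtype=bool) & mask
    if not mask.any():
        raise ValueError("breast mask is empty")
    healthy = mask & ~tumor_roi
    intens = ce_baseline.values[healthy]
    if np.unique(intens).size < 2:
        raise ValueError("fewer than 2 distinct intensities in the healthy tissue")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assign = km.fit_predict(intens.reshape(-1, 1))
    centers = km.cluster_centers_.ravel()
    low_cluster = int(np.argmin(centers))
    if adipose_is_lower_intensity:
        adipose_cluster = low_cluster
    else:
        adipose_cluster = 1 - low_cluster
    labels = np.zeros(mask.shape, dtype=np.float64)
    lab_healthy = np.where(assign == adipose_cluster, LABEL_ADIPOSE, LABEL_FIBROGLANDULAR)
    labels[healthy] = lab_healthy
    labels[tumor_roi] = LABEL_TUMOR
    return BreastDomain(
        mask=ce_baseline.with_values(mask.astype(np.float64)),
        tissue_labels=ce_baseline.with_values(labels),
    )


# ---------------------------------------------------------------------------
# Drug-distribution maps


def compute_auc_drug_map(
    ce_stack: Sequence[ImageVolume],
    baseline_index: int,
    roi: np.ndarray,
    frame_interval_s: float = 180.0,
    breast_mask: np.ndarray | None = None,
) -> ImageVolume:
    """Normalized post-injection area-under-the-curve map in [0, 1].

    Enhancement is signal minus the average baseline; its trapezoidal AUC
    over post-injection frames (negatives floored at 0) is divided by the
    maximum AUC within ``roi``.
    """
    n = len(ce_stack)
    if baseline_index >= n - 1:
        raise ValueError("need at least one post-contrast frame")
    baseline = np.mean([v.values for v in ce_stack[: baseline_index + 1]], axis=0)
    post = np.stack([v.values for v in ce_stack[baseline_index + 1 :]], axis=-1)
    enh = np.clip(post - baseline[..., None], 0.0, None)
    auc = np.trapezoid(enh, dx=frame_interval_s, axis=-1) if enh.shape[-1] > 1 else (
        enh[..., 0] * frame_interval_s
    )
    roi = np.asarray(roi, dtype=bool)
    max_auc = auc[roi].max() if roi.any() else 0.0
    if max_auc <= 0:
        raise ValueError("maximum AUC within the ROI is zero")
    out = np.clip(auc / max_auc, 0.0, 1.0)
    if breast_mask is not None:
        out = np.where(np.asarray(breast_mask, dtype=bool), out, 0.0)
    return ce_stack[0].with_values(out)


def normalize_pet_map(
    pet: ImageVolume, roi: np.ndarray, breast_mask: np.ndarray | None = None
) -> ImageVolume:
    """PET uptake divided by its maximum over ``roi``, clipped to [0, 1]."""
    roi = np.asarray(roi, dtype=bool)
    peak = pet.values[roi].max() if roi.any() else 0.0
    if peak <= 0:
        raise ValueError("maximum PET uptake within the ROI is nonpositive")
    out = np.clip(pet.values / peak, 0.0, 1.0)
    if breast_mask is not None:
        out = np.where(np.asarray(breast_mask, dtype=bool), out, 0.0)
    return pet.with_values(out)


# ---------------------------------------------------------------------------
# Cellularity


def carrying_capacity(
    voxel_volume_mm3: float, packing_fraction: float = 0.74, cell_radius_um: float = 10.0
) -> float:
    """Maximum cells per voxel from sphere-packing geometry.

    theta = packing_fraction * voxel_volume / cell_volume with the cell a
    sphere of the given radius.
    """
    if voxel_volume_mm3 <= 0 or packing_fraction <= 0 or cell_radius_um <= 0:
        raise ValueError("all carrying-capacity inputs must be positive")
    r_mm = cell_radius_um * 1e-3
    cell_volume = 4.0 / 3.0 * np.pi * r_mm**3
    return packing_fraction * voxel_volume_mm3 / cell_volume


def cellularity_from_adc(
    adc: ImageVolume,
    roi: np.ndarray,
    theta: float,
    adc_w: float = 3.0e-3,
    adc_min: float | None = None,
) -> CellularityMap:
    """Tumor cells per voxel from the linear ADC-to-cellularity map.

    counts = theta * (adc_w - ADC) / (adc_w - ADC_min) inside the ROI,
    clipped to [0, theta]; zero outside.  ``adc_min`` defaults to the
    minimum ADC over the ROI (the per-patient reference).
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("ROI is empty")
    if adc_min is None:
        adc_min = float(adc.values[roi].min())
    if adc_min >= adc_w:
        raise ValueError(
            f"ADC_min ({adc_min:g}) >= ADC_w ({adc_w:g}): degenerate tumor ROI"
        )
    counts = theta * (adc_w - adc.values) / (adc_w - adc_min)
    counts = np.where(roi, np.clip(counts, 0.0, theta), 0.0)
    return CellularityMap(adc.with_values(counts), theta, roi)


def tumor_volume(
    roi_or_map: np.ndarray | CellularityMap,
    voxel_volume_mm3: float,
    threshold_fraction: float = 0.25,
) -> float:
    """Tumor volume in mm^3: voxel count times voxel volume.

    For a predicted cellularity map, voxels with counts at or above
    ``threshold_fraction * theta`` are counted.
    """
    if voxel_volume_mm3 <= 0:
        raise ValueError("voxel_volume must be positive")
    if isinstance(roi_or_map, CellularityMap):
        n = int(
            np.count_nonzero(
                roi_or_map.counts.values >= threshold_fraction * roi_or_map.theta
            )
        )
    else:
        n = int(np.count_nonzero(np.asarray(roi_or_map, dtype=bool)))
    return n * voxel_volume_mm3
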