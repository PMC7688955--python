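"""Volumetric data model, NIfTI I/O, resampling, and run configuration.

Conventions used throughout the package:

* axis order is fixed ``(i, j, k) -> (x, y, z)``;
* the grid is voxel-centered with 0-based indices, so the physical
  position of voxel ``(i, j, k)`` is ``origin + index * spacing``;
* time is measured in days with scan 1 defining ``t = 0``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml
from scipy.ndimage import map_coordinates

__all__ = [
    "ImageVolume",
    "BreastDomain",
    "TreatmentSchedule",
    "StudyConfig",
    "read_volume",
    "write_volume",
    "downsample_by_factor",
    "resample_to_grid",
    "load_config",
]

#: tolerance (mm) for grid compatibility checks
GRID_TOL = 1e-6

# tissue label codes
LABEL_OUTSIDE = 0
LABEL_ADIPOSE = 1
LABEL_FIBROGLANDULAR = 2
LABEL_TUMOR = 3


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar field on a regular grid with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar samples at voxel centers (units depend on role).
    spacing : tuple of float
        Voxel spacing ``(dx, dy, dz)`` in mm; strictly positive.
    origin : tuple of float
        Physical position of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3D array, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("ImageVolume values must all be finite")
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 strictly positive components, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.spacing))

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """Same grid, new samples."""
        return ImageVolume(values, self.spacing, self.origin)

    def is_grid_compatible(self, other: "ImageVolume", tol: float = GRID_TOL) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def physical_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (lower, upper) corners of the sampled region in mm."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi


@dataclass(frozen=True)
class BreastDomain:
    """Breast mask plus tissue labels (0=outside, 1=adipose, 2=fibroglandular, 3=tumor)."""

    mask: ImageVolume
    tissue_labels: ImageVolume

    def __post_init__(self) -> None:
        mask = self.mask.with_values(self.mask.values.astype(bool).astype(np.float64))
        labels = self.tissue_labels
        if not mask.is_grid_compatible(labels):
            raise ValueError("mask and tissue_labels must share one grid")
        m = mask.values.astype(bool)
        lab = labels.values.astype(int)
        if not np.array_equal(lab != LABEL_OUTSIDE, m):
            raise ValueError("tissue_labels must be nonzero exactly where mask is true")
        object.__setattr__(self, "mask", mask)

    @property
    def mask_array(self) -> np.ndarray:
        return self.mask.values.astype(bool)

    @property
    def labels_array(self) -> np.ndarray:
        return self.tissue_labels.values.astype(int)

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels_array == LABEL_TUMOR


@dataclass(frozen=True)
class TreatmentSchedule:
    """Dose and milestone times in days relative to scan 1 (= day 0)."""

    dose_times: tuple[float, ...]
    scan1_time: float
    scan2_time: float
    surgery_time: float
    n_chemo_drugs: int = 2

    def __post_init__(self) -> None:
        doses = tuple(float(t) for t in self.dose_times)
        if any(b < a for a, b in zip(doses, doses[1:])):
            raise ValueError("dose_times must be sorted ascending")
        if not (self.scan1_time == 0.0 <= self.scan2_time < self.surgery_time):
            raise ValueError(
                "schedule must satisfy scan1_time = 0 <= scan2_time < surgery_time"
            )
        object.__setattr__(self, "dose_times", doses)

    def doses_before(self, t: float) -> tuple[float, ...]:
        return tuple(td for td in self.dose_times if td <= t)


@dataclass
class StudyConfig:
    """Fixed model constants and run knobs.

    Defaults are the study's assigned values; ``theta_override`` replaces the
    packing-fraction carrying capacity when the working grid differs from the
    one used to derive it.
    """

    gamma: float = 2.0e-3            # stress-diffusion coupling, 1/kPa
    nu: float = 0.45                 # Poisson's ratio
    lam: float = 2.5e-3              # cell-gradient force coupling (dimensionless)
    youngs_modulus: dict = field(
        default_factory=lambda: {"adipose": 2.0, "fibroglandular": 4.0, "tumor": 20.0}
    )                                # kPa per tissue
    dt: float = 0.25                 # day
    adc_w: float = 3.0e-3            # ADC of free water at 37C, mm^2/s
    packing_fraction: float = 0.74
    cell_radius_um: float = 10.0
    voxel_volume_mm3: float = 2.18   # explicit input; the modeling grid is a knob
    theta_override: float | None = None
    volume_threshold_fraction: float = 0.25
    mechanics_cadence: int = 1       # recompute elasticity every N steps
    membership_threshold: float = 0.5
    fcm_classes: int = 2
    adipose_is_lower_intensity: bool = True
    ce_frame_interval_s: float = 180.0
    # calibration bounds inputs (half-lives in days; literature-range knobs)
    chemo_half_life_days: dict = field(
        default_factory=lambda: {"drug1": (0.5, 10.0), "drug2": (0.5, 10.0)}
    )
    alpha_cap: float = 5.0           # 1/day
    k_cap: float = 0.5               # 1/day
    seed: int = 0

    def young_modulus_by_label(self) -> np.ndarray:
        """E (kPa) indexed by tissue label code; label 0 gets adipose stiffness."""
        e = self.youngs_modulus
        return np.array([e["adipose"], e["adipose"], e["fibroglandular"], e["tumor"]])


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(vol: ImageVolume) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vol.spacing
    aff[:3, 3] = vol.origin
    return aff


def read_volume(path: str | Path, component: int | None = None) -> ImageVolume:
    """Read a NIfTI-1 volume; ``component`` selects a 3D frame from 4D data."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format errors
        raise ValueError(f"{path} is not a readable NIfTI volume: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if component is None:
            raise ValueError(f"{path} is 4D; pass component= to select a 3D frame")
        data = data[..., component]
    elif data.ndim != 3:
        raise ValueError(f"{path} has unsupported dimensionality {data.ndim}")
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    origin = tuple(float(v) for v in aff[:3, 3])
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def read_stack(path: str | Path) -> list[ImageVolume]:
    """Read a 4D NIfTI as an indexed list of 3D volumes."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        data = data[..., np.newaxis]
    if data.ndim != 4:
        raise ValueError(f"{path} has unsupported dimensionality {data.ndim}")
    aff = img.affine
    spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
    origin = tuple(float(v) for v in aff[:3, 3])
    return [
        ImageVolume(np.asarray(data[..., i], dtype=np.float64), spacing, origin)
        for i in range(data.shape[-1])
    ]


def write_volume(vol: ImageVolume, path: str | Path, dtype: str = "float64") -> None:
    """Write a NIfTI-1 file readable by :func:`read_volume`."""
    path = Path(path)
    if path.is_dir():
        raise IsADirectoryError(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory {path.parent} does not exist")
    img = nib.Nifti1Image(vol.values.astype(dtype), _affine(vol))
    nib.save(img, str(path))


def write_stack(vols: Sequence[ImageVolume], path: str | Path, dtype: str = "float64") -> None:
    """Write a list of grid-compatible 3D volumes as one 4D NIfTI."""
    first = vols[0]
    for v in vols[1:]:
        if not first.is_grid_compatible(v):
            raise ValueError("stack members must be grid-compatible")
    data = np.stack([v.values for v in vols], axis=-1).astype(dtype)
    nib.save(nib.Nifti1Image(data, _affine(first)), str(Path(path)))


# ---------------------------------------------------------------------------
# Resampling


def downsample_by_factor(vol: ImageVolume, factor: int, mode: str = "mean") -> ImageVolume:
    """Block-average (or block-sum) down-sampling by an integer factor.

    ``mode="sum"`` conserves totals and is the right choice for cell-count
    volumes; ``mode="mean"`` is for intensity volumes.  Shapes not divisible
    by ``factor`` are zero-padded on the high side first.
    """
    if int(factor) != factor or factor <= 0:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    factor = int(factor)
    if mode not in ("mean", "sum"):
        raise ValueError(f"mode must be 'mean' or 'sum', got {mode!r}")
    v = vol.values
    pad = [(0, (-s) % factor) for s in v.shape]
    if any(p[1] for p in pad):
        v = np.pad(v, pad, mode="constant")
    nx, ny, nz = (s // factor for s in v.shape)
    blocks = v.reshape(nx, factor, ny, factor, nz, factor)
    if mode == "sum":
        out = blocks.sum(axis=(1, 3, 5))
    else:
        out = blocks.mean(axis=(1, 3, 5))
    spacing = tuple(s * factor for s in vol.spacing)
    # voxel-centered: the coarse center sits mid-block
    origin = tuple(
        o + (factor - 1) / 2.0 * s for o, s in zip(vol.origin, vol.spacing)
    )
    return ImageVolume(out, spacing, origin)


def resample_to_grid(vol: ImageVolume, target: ImageVolume) -> ImageVolume:
    """Trilinear interpolation of ``vol`` at the voxel centers of ``target``.

    Points outside the source extent are filled with 0.  Raises if the two
    physical extents are disjoint.
    """
    lo_s, hi_s = vol.physical_extent()
    lo_t, hi_t = target.physical_extent()
    if np.any(hi_s < lo_t) or np.any(hi_t < lo_s):
        raise ValueError("source and target physical extents are disjoint")
    axes = [
        target.origin[d] + np.arange(target.shape[d]) * target.spacing[d]
        for d in range(3)
    ]
    px, py, pz = np.meshgrid(*axes, indexing="ij")
    # physical -> fractional source index
    coords = [
        (p - vol.origin[d]) / vol.spacing[d] for d, p in enumerate((px, py, pz))
    ]
    out = map_coordinates(vol.values, coords, order=1, mode="constant", cval=0.0)
    return ImageVolume(out, target.spacing, target.origin)


# ---------------------------------------------------------------------------
# Run configuration


def _schedule_from_dict(d: dict) -> TreatmentSchedule:
    return TreatmentSchedule(
        dose_times=tuple(d["dose_times"]),
        scan1_time=float(d.get("scan1_time", 0.0)),
        scan2_time=float(d["scan2_time"]),
        surgery_time=float(d["surgery_time"]),
        n_chemo_drugs=int(d.get("n_chemo_drugs", 2)),
    )


def load_config(path: str | Path) -> dict:
    """Load a YAML run config into ``{"study": StudyConfig, "schedule": ..., ...}``.

    Unknown top-level keys (file paths, b-values, synthetic-patient blocks)
    are passed through untouched.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    study_kwargs = raw.pop("study", {})
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(study_kwargs) - known
    if unknown:
        raise ValueError(f"unknown study-config keys: {sorted(unknown)}")
    # PyYAML parses exponents like "2.02e6" (no sign) as strings; coerce
    for key, value in list(study_kwargs.items()):
        if isinstance(value, str):
            try:
                study_kwargs[key] = float(value)
            except ValueError:
                pass
    if "youngs_modulus" in study_kwargs:
        study_kwargs["youngs_modulus"] = dict(study_kwargs["youngs_modulus"])
    if "chemo_half_life_days" in study_kwargs:
        study_kwargs["chemo_half_life_days"] = {
            k: tuple(v) for k, v in study_kwargs["chemo_half_life_days"].items()
        }
    out = {"study": StudyConfig(**study_kwargs)}
    if "schedule" in raw:
        out["schedule"] = _schedule_from_dict(raw.pop("schedule"))
    out.update(raw)
    return out
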