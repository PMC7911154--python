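"""SUV conversion, reference ROI, and threshold-based tumor delineation.

Activity images (Bq/mL) are converted voxelwise to standardized uptake
values, SUV = activity × body_weight / injected_dose.  A spherical
reference region (default 10 mm diameter) on normal contralateral tissue
yields the reference SUVmean; the tumor boundary is delineated as the
26-connected supra-threshold component (default threshold 1.3 × reference
SUVmean) containing the hottest candidate voxel.  From the boundary the
semi-quantitative metrics SUVmax, SUVmean, TNR (= SUVmax / reference),
MTV (mL) and TLMU (= MTV × SUVmean) are computed.

Coordinates are 0-based voxel indices; physical geometry enters only
through the voxel spacing (axis-aligned grids, no affine orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ActivityVolume",
    "DoseInfo",
    "SUVVolume",
    "ReferenceROI",
    "TumorSegmentation",
    "EmptySegmentationError",
    "to_suv",
    "sphere_mask",
    "reference_suvmean",
    "segment_tumor",
]

#: 3x3x3 all-ones structuring element: 26-connectivity.
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)

#: Default delineation threshold as a multiple of the reference SUVmean.
DEFAULT_THRESHOLD_MULTIPLE = 1.3

#: Masks smaller than this raise; below WARN_VOXELS a warning is attached
#: downstream (64-level texture matrices degenerate on tiny regions).
MIN_TEXTURE_VOXELS = 27
WARN_TEXTURE_VOXELS = 64


class EmptySegmentationError(ValueError):
    """No voxel reaches the delineation threshold."""

    def __init__(self, threshold: float):
        self.threshold = threshold
        super().__init__(
            f"no voxel reaches the delineation threshold (SUV >= {threshold:g})"
        )


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be 3 strictly positive values, got {spacing}")
    return spacing


@dataclass(frozen=True)
class ActivityVolume:
    """3D grid of tissue radioactivity in Bq/mL with voxel spacing in mm."""

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "voxel_spacing", _check_spacing(self.voxel_spacing))
        if self.values.ndim != 3:
            raise ValueError("activity volume must be 3D")
        if np.any(self.values < 0):
            raise ValueError("activity values must be non-negative")


@dataclass(frozen=True)
class DoseInfo:
    """Injected-dose normalization factors: body weight (g), dose (Bq)."""

    body_weight_g: float
    injected_dose_bq: float

    def __post_init__(self):
        if self.body_weight_g <= 0 or self.injected_dose_bq <= 0:
            raise ValueError("body weight and injected dose must be strictly positive")


@dataclass(frozen=True)
class SUVVolume:
    """3D grid of standardized uptake values (dimensionless)."""

    values: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self):
        object.__setattr__(self, "voxel_spacing", _check_spacing(self.voxel_spacing))
        if self.values.ndim != 3:
            raise ValueError("SUV volume must be 3D")


@dataclass(frozen=True)
class ReferenceROI:
    """Spherical reference region: center in voxel indices, diameter in mm."""

    center: tuple[int, int, int]
    diameter_mm: float = 10.0

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("ROI diameter must be positive")


@dataclass
class TumorSegmentation:
    """Supra-threshold tumor boundary plus its semi-quantitative metrics.

    Every masked voxel satisfies SUV >= threshold_multiple × reference_suvmean.
    mtv_ml is the masked volume in mL (mm³/1000); tlmu = mtv_ml × suvmean.
    """

    mask: np.ndarray
    reference_suvmean: float
    suvmax: float
    suvmean: float
    tnr: float
    mtv_ml: float
    tlmu: float
    voxel_spacing: tuple[float, float, float]
    threshold_multiple: float = DEFAULT_THRESHOLD_MULTIPLE
    warnings: list[str] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def to_suv(vol: ActivityVolume, dose: DoseInfo) -> SUVVolume:
    """Convert activity (Bq/mL) to SUV = activity × body weight (g) / dose (Bq)."""
    suv = vol.values * (dose.body_weight_g / dose.injected_dose_bq)
    return SUVVolume(values=suv, voxel_spacing=vol.voxel_spacing)


def sphere_mask(shape, spacing, center_voxel, diameter_mm: float) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the sphere.

    Membership is decided by voxel-center distance (<= radius), the simplest
    unambiguous rasterization.
    """
    spacing = _check_spacing(spacing)
    radius = diameter_mm / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) * sp) ** 2 for g, c, sp in zip(grids, center_voxel, spacing))
    return d2 <= radius**2


def reference_suvmean(suv: SUVVolume, roi: ReferenceROI) -> float:
    """Mean SUV over voxels whose centers fall inside the reference sphere."""
    center = roi.center
    radius_vox = [roi.diameter_mm / 2.0 / s for s in suv.voxel_spacing]
    for c, r, n in zip(center, radius_vox, suv.values.shape):
        if c - r < -0.5 or c + r > n - 0.5:
            raise ValueError("reference ROI sphere extends outside the image grid")
    mask = sphere_mask(suv.values.shape, suv.voxel_spacing, center, roi.diameter_mm)
    if not mask.any():
        raise ValueError("reference ROI sphere contains no voxel centers")
    return float(suv.values[mask].mean())


def segment_tumor(
    suv: SUVVolume,
    ref: float,
    search_region: tuple[slice, slice, slice] | None = None,
    threshold_multiple: float = DEFAULT_THRESHOLD_MULTIPLE,
) -> TumorSegmentation:
    """Delineate the tumor at ``threshold_multiple`` × reference SUVmean.

    Candidate voxels are those with SUV >= threshold (inclusive), restricted
    to ``search_region`` if given.  The returned mask is the 26-connected
    candidate component containing the candidates' global SUV maximum — an
    automated stand-in for physician selection of the MET-avid area, with
    ``search_region`` as the manual-review hook.
    """
    if ref <= 0:
        raise ValueError("reference SUVmean must be strictly positive")
    if threshold_multiple <= 0:
        raise ValueError("threshold multiple must be strictly positive")
    threshold = threshold_multiple * ref

    candidates = suv.values >= threshold
    if search_region is not None:
        restricted = np.zeros_like(candidates)
        restricted[search_region] = candidates[search_region]
        candidates = restricted
    if not candidates.any():
        raise EmptySegmentationError(threshold)

    labels, _ = ndimage.label(candidates, structure=CONNECTIVITY_26)
    masked_vals = np.where(candidates, suv.values, -np.inf)
    peak = np.unravel_index(int(np.argmax(masked_vals)), suv.values.shape)
    mask = labels == labels[peak]

    vals = suv.values[mask]
    suvmax = float(vals.max())
    suvmean = float(vals.mean())
    voxel_volume_ml = float(np.prod(suv.voxel_spacing)) / 1000.0
    mtv_ml = float(mask.sum()) * voxel_volume_ml
    warnings_ = []
    n = int(mask.sum())
    if n < MIN_TEXTURE_VOXELS:
        warnings_.append(
            f"mask has {n} voxels (< {MIN_TEXTURE_VOXELS}); texture matrices will be degenerate"
        )
    elif n < WARN_TEXTURE_VOXELS:
        warnings_.append(
            f"mask has {n} voxels (< {WARN_TEXTURE_VOXELS}); 64-level texture may be unstable"
        )
    return TumorSegmentation(
        mask=mask,
        reference_suvmean=float(ref),
        suvmax=suvmax,
        suvmean=suvmean,
        tnr=suvmax / float(ref),
        mtv_ml=mtv_ml,
        tlmu=mtv_ml * suvmean,
        voxel_spacing=suv.voxel_spacing,
        threshold_multiple=threshold_multiple,
        warnings=warnings_,
    )
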