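"""Per-lesion measurements: concentration metrics, volumes, recovery.

Concentration metrics follow the usual PET naming (kept even though the
phantom work stays in kBq/mL rather than dose-normalised SUV):

* ``max``  — hottest voxel of the lesion mask (a single voxel);
* ``peak`` — mean of a 1-mL spherical ROI centred at the max voxel;
* ``apex`` — mean of a 0.26-mL spherical ROI centred at the max voxel,
  a hybrid sized for focal sub-mL lesions (~6 voxels on the default grid);
* ``mean`` — weight-aware mean over a segmentation mask.

Spherical ROIs use fractional voxel weights and reproduce their nominal
volume to 1e-6 relative by blending two nearby rasterized radii (ROI volume
is linear in the weights, so the blend is exact).

Recovery coefficient: RC = a_meas / a_true × 100.  Total tumour uptake:
TTU = a_mean × MTV.  Ground truth comes from a cold scan (background fully
decayed): total activity in a 40-mm spherical ROI divided by the known
lesion volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import ActivityImage, VoxelGrid
from .phantom import rasterize_sphere
from .segmentation import SegmentationMask

__all__ = [
    "GroundTruth",
    "LesionMetrics",
    "ContrastNoiseMetrics",
    "ClippedROIError",
    "spherical_roi",
    "measure_max",
    "measure_mean",
    "measure_peak",
    "measure_apex",
    "mtv",
    "ttu",
    "recovery_coefficient",
    "ground_truth_from_cold_scan",
    "measure_lesion",
    "contrast_and_noise",
]

APEX_VOLUME_ML = 0.26
PEAK_VOLUME_ML = 1.0
GROUND_TRUTH_ROI_DIAMETER_MM = 40.0


class ClippedROIError(ValueError):
    """A spherical ROI would extend beyond the image bounds."""


@dataclass(frozen=True)
class GroundTruth:
    lesion_id: str
    a_true: float  # kBq/mL
    true_volume: float  # mL

    def __post_init__(self):
        if not self.a_true > 0 or not self.true_volume > 0:
            raise ValueError("ground truth concentration and volume must be positive")


@dataclass(frozen=True)
class LesionMetrics:
    lesion_id: str
    a_max: float
    a_mean: float
    a_peak: float
    a_apex: float
    MTV: float
    TTU: float
    RC_max: float | None = None
    RC_mean: float | None = None
    RC_peak: float | None = None
    RC_apex: float | None = None


@dataclass(frozen=True)
class ContrastNoiseMetrics:
    a_bkg: float
    sigma_bkg: float
    C_max: float
    C_mean: float
    CNR_max: float
    CNR_mean: float
    SNR_max: float
    SNR_mean: float


# ---------------------------------------------------------------------------
# Spherical ROIs with exact fractional volume
# ---------------------------------------------------------------------------


def spherical_roi(grid: VoxelGrid, center_mm, volume_ml: float) -> np.ndarray:
    """Fractional weights of a sphere at ``center_mm`` with exact volume.

    The radius is bracketed around the nominal (3V/4π)^(1/3) and two nearby
    rasterizations are blended so that Σw·voxel_volume = volume_ml to 1e-6
    relative.

    Raises
    ------
    ClippedROIError
        If the nominal sphere does not fit inside the grid.
    """
    if volume_ml <= 0:
        raise ValueError("ROI volume must be positive")
    center = np.asarray(center_mm, dtype=float)
    r0 = (3.0 * volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    lo_world = grid.index_to_world((-0.5, -0.5, -0.5))
    hi_world = grid.index_to_world(tuple(n - 0.5 for n in grid.shape))
    if np.any(center - r0 < lo_world) or np.any(center + r0 > hi_world):
        raise ClippedROIError(
            f"{volume_ml} mL ROI at {tuple(center)} extends beyond the image"
        )

    def vol(r):
        return rasterize_sphere(grid, center, 2.0 * r).sum() * grid.voxel_volume

    r_lo, r_hi = 0.9 * r0, 1.1 * r0
    while vol(r_lo) > volume_ml:
        r_lo *= 0.9
    while vol(r_hi) < volume_ml:
        r_hi *= 1.1
    for _ in range(30):
        mid = 0.5 * (r_lo + r_hi)
        if vol(mid) < volume_ml:
            r_lo = mid
        else:
            r_hi = mid
    w_lo = rasterize_sphere(grid, center, 2.0 * r_lo)
    w_hi = rasterize_sphere(grid, center, 2.0 * r_hi)
    v_lo = w_lo.sum() * grid.voxel_volume
    v_hi = w_hi.sum() * grid.voxel_volume
    if v_hi == v_lo:
        return w_hi
    t = (volume_ml - v_lo) / (v_hi - v_lo)
    return (1.0 - t) * w_lo + t * w_hi


# ---------------------------------------------------------------------------
# Concentration metrics
# ---------------------------------------------------------------------------


def _weights_of(mask) -> np.ndarray:
    if isinstance(mask, SegmentationMask):
        return mask.weights
    return np.asarray(mask, dtype=float)


def measure_max(image: ActivityImage, search_mask) -> float:
    """Maximum over voxels with positive mask weight."""
    w = _weights_of(search_mask)
    support = w > 0
    if not support.any():
        raise ValueError("mask is empty")
    return float(image.values[support].max())


def measure_mean(image: ActivityImage, mask) -> float:
    """Weight-aware mean Σ w·v / Σ w (plain average for a binary mask)."""
    w = _weights_of(mask)
    total = w.sum()
    if total <= 0:
        raise ValueError("mask is empty")
    return float((w * image.values).sum() / total)


def _max_voxel_center(image: ActivityImage, search_mask=None) -> np.ndarray:
    vals = image.values
    if search_mask is not None:
        w = _weights_of(search_mask)
        if not (w > 0).any():
            raise ValueError("search mask is empty")
        masked = np.where(w > 0, vals, -np.inf)
    else:
        masked = vals
    idx = np.unravel_index(int(np.argmax(masked)), vals.shape)
    return np.asarray(image.grid.index_to_world(idx), dtype=float)


def measure_peak(
    image: ActivityImage,
    search_mask=None,
    volume_ml: float = PEAK_VOLUME_ML,
    maximize_mean: bool = False,
) -> float:
    """Mean of a fractional spherical ROI of ``volume_ml`` (default 1 mL).

    Centred at the hottest voxel by default.  With ``maximize_mean`` the
    centre is instead chosen among the 3³ voxel centres around the hottest
    voxel to maximize the ROI mean (a stricter reading of peak used by some
    tools; off by default to match the apex centring convention).
    """
    center = _max_voxel_center(image, search_mask)
    if not maximize_mean:
        roi = spherical_roi(image.grid, center, volume_ml)
        return measure_mean(image, roi)
    best = -np.inf
    spacing = np.asarray(image.grid.spacing)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                c = center + spacing * (dx, dy, dz)
                try:
                    roi = spherical_roi(image.grid, c, volume_ml)
                except ClippedROIError:
                    continue
                best = max(best, measure_mean(image, roi))
    if best == -np.inf:
        raise ClippedROIError("no valid peak ROI placement")
    return float(best)


def measure_apex(
    image: ActivityImage,
    search_mask=None,
    volume_ml: float = APEX_VOLUME_ML,
) -> float:
    """Mean of a 0.26-mL fractional spherical ROI centred at the max voxel."""
    center = _max_voxel_center(image, search_mask)
    roi = spherical_roi(image.grid, center, volume_ml)
    return measure_mean(image, roi)


def mtv(mask) -> float:
    """Metabolic tumour volume: Σ weights × voxel volume, in mL."""
    if isinstance(mask, SegmentationMask):
        return mask.volume_ml
    raise TypeError("mtv expects a SegmentationMask")


def ttu(a_mean: float, mtv_ml: float) -> float:
    """Total tumour uptake = a_mean × MTV (kBq)."""
    return a_mean * mtv_ml


def recovery_coefficient(a_meas: float, a_true: float) -> float:
    """RC = a_meas / a_true × 100 (percent)."""
    if a_true <= 0:
        raise ValueError("a_true must be positive")
    return a_meas / a_true * 100.0


def ground_truth_from_cold_scan(
    cold_image: ActivityImage,
    lesion_center,
    true_volume: float,
    lesion_id: str = "",
    roi_diameter: float = GROUND_TRUTH_ROI_DIAMETER_MM,
    other_lesion_centers=(),
) -> GroundTruth:
    """Lesion concentration from a scan with fully decayed background.

    a_true = (total activity in a 40-mm spherical ROI) / true volume.  The
    generous ROI captures PSF spill-out, so the estimate is blur-invariant.
    Emits a warning if another lesion's 40-mm ROI overlaps this one.
    """
    if true_volume <= 0:
        raise ValueError("true_volume must be positive")
    center = np.asarray(lesion_center, dtype=float)
    for other in other_lesion_centers:
        if np.linalg.norm(center - np.asarray(other)) < roi_diameter:
            warnings.warn(
                f"40-mm ground-truth ROIs overlap between lesions at {tuple(center)} "
                f"and {tuple(other)}; activity may be contaminated",
                stacklevel=2,
            )
    roi = rasterize_sphere(cold_image.grid, center, roi_diameter)
    total_kbq = float((roi * cold_image.values).sum() * cold_image.grid.voxel_volume)
    return GroundTruth(lesion_id=lesion_id or "lesion", a_true=total_kbq / true_volume, true_volume=true_volume)


def measure_lesion(
    image: ActivityImage,
    mask: SegmentationMask,
    ground_truth: GroundTruth | None = None,
) -> LesionMetrics:
    """All concentration/volume metrics for one lesion mask, with RCs if a
    ground truth is supplied."""
    a_max = measure_max(image, mask)
    a_mean = measure_mean(image, mask)
    a_peak = measure_peak(image, mask)
    a_apex = measure_apex(image, mask)
    vol = mtv(mask)
    rc = {}
    if ground_truth is not None:
        rc = {
            "RC_max": recovery_coefficient(a_max, ground_truth.a_true),
            "RC_mean": recovery_coefficient(a_mean, ground_truth.a_true),
            "RC_peak": recovery_coefficient(a_peak, ground_truth.a_true),
            "RC_apex": recovery_coefficient(a_apex, ground_truth.a_true),
        }
    return LesionMetrics(
        lesion_id=ground_truth.lesion_id if ground_truth else "lesion",
        a_max=a_max,
        a_mean=a_mean,
        a_peak=a_peak,
        a_apex=a_apex,
        MTV=vol,
        TTU=ttu(a_mean, vol),
        **rc,
    )


def contrast_and_noise(
    image: ActivityImage,
    a_max: float,
    a_mean: float,
    bkg_roi_centers,
    roi_volume_ml: float = 0.5,
    lesion_support: np.ndarray | None = None,
) -> ContrastNoiseMetrics:
    """Contrast, CNR and SNR from five 0.5-mL background ROIs.

    a_bkg is the mean of the ROI means and σ_bkg their sample SD (between-ROI,
    not within-ROI voxel SD).  By construction SNR − CNR = a_bkg/σ_bkg for
    both the max and mean variants.
    """
    centers = [np.asarray(c, dtype=float) for c in bkg_roi_centers]
    if len(centers) < 2:
        raise ValueError("need at least two background ROIs (five by protocol)")
    r = (3.0 * roi_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    for i, a in enumerate(centers):
        for b in centers[i + 1:]:
            if np.linalg.norm(a - b) < 2.0 * r:
                raise ValueError("background ROIs overlap each other")
    means = []
    for c in centers:
        roi = spherical_roi(image.grid, c, roi_volume_ml)
        if lesion_support is not None and np.any(roi[lesion_support] > 0):
            raise ValueError(f"background ROI at {tuple(c)} intersects a lesion")
        means.append(measure_mean(image, roi))
    means = np.asarray(means)
    a_bkg = float(means.mean())
    sigma_bkg = float(means.std(ddof=1))
    if a_bkg <= 0 or sigma_bkg <= 0:
        raise ValueError("degenerate background (zero mean or zero variance)")
    return ContrastNoiseMetrics(
        a_bkg=a_bkg,
        sigma_bkg=sigma_bkg,
        C_max=a_max / a_bkg * 100.0,
        C_mean=a_mean / a_bkg * 100.0,
        CNR_max=(a_max - a_bkg) / sigma_bkg,
        CNR_mean=(a_mean - a_bkg) / sigma_bkg,
        SNR_max=a_max / sigma_bkg,
        SNR_mean=a_mean / sigma_bkg,
    )
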