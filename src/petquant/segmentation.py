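"""Lesion delineation: 40 %-of-max fixed threshold and gradient segmentation.

Both methods start from a user seed inside the lesion and hill-climb to the
local maximum; the threshold reference is that *local* maximum, not the image
maximum, so a nearby hot organ cannot hijack a lesion's threshold.

The fixed-threshold method keeps whole voxels: the face-connected component,
containing the local maximum, of voxels ≥ fraction × local-max.

The gradient method finds the lesion boundary at the inflection of the
activity profile: line profiles are cast along quasi-uniform (spherical
Fibonacci) directions, interpolated at sub-voxel steps, lightly smoothed, and
the boundary radius per ray is the first zero-crossing of the second
derivative at/beyond the steepest-descent point.  The per-ray radii are
smoothed over neighbouring directions and the resulting star-convex surface
is converted to fractional voxel weights with the same supersampler used for
phantom rasterization — so the output mask is sub-voxel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import ActivityImage, VoxelGrid
from .phantom import SUPERSAMPLE, _subcell_offsets

__all__ = [
    "SeedPoint",
    "SegmentationMask",
    "SegmentationError",
    "EmptySegmentationError",
    "NoBoundaryError",
    "hill_climb",
    "segment_fixed_threshold",
    "segment_gradient",
]

FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


class SegmentationError(RuntimeError):
    pass


class EmptySegmentationError(SegmentationError):
    """Seed fell in a zero-valued region; no lesion to delineate."""


class NoBoundaryError(SegmentationError):
    """No inflection point found within the search radius."""


@dataclass(frozen=True)
class SeedPoint:
    """A world coordinate (mm) expected to lie inside the lesion."""

    location: tuple[float, float, float]


@dataclass
class SegmentationMask:
    """Per-voxel inclusion weights in [0, 1] with provenance."""

    grid: VoxelGrid
    weights: np.ndarray
    method: str
    seed: SeedPoint
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != self.grid.shape:
            raise ValueError("weights shape does not match grid")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def volume_ml(self) -> float:
        return float(self.weights.sum() * self.grid.voxel_volume)

    @property
    def support(self) -> np.ndarray:
        return self.weights > 0


def hill_climb(image: ActivityImage, seed: SeedPoint) -> tuple[int, int, int]:
    """Greedy 26-neighbourhood ascent from the seed to a local maximum.

    Ties break on the lowest linear index, making the result deterministic.
    """
    idx = np.array(image.grid.world_to_nearest_voxel(seed.location))
    vals = image.values
    shape = np.asarray(vals.shape)
    while True:
        lo = np.maximum(idx - 1, 0)
        hi = np.minimum(idx + 2, shape)
        patch = vals[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        # argmax picks the lowest flat index on ties; within the patch that is
        # also the lowest global linear index, giving the deterministic tie-break
        best = np.array(np.unravel_index(int(np.argmax(patch)), patch.shape)) + lo
        if tuple(best) == tuple(idx):
            return tuple(int(i) for i in idx)
        here = vals[tuple(idx)]
        there = vals[tuple(best)]
        moves = there > here or (
            there == here
            and np.ravel_multi_index(tuple(best), vals.shape)
            < np.ravel_multi_index(tuple(idx), vals.shape)
        )
        if not moves:
            return tuple(int(i) for i in idx)
        idx = best


def segment_fixed_threshold(
    image: ActivityImage,
    seed: SeedPoint,
    fraction: float = 0.40,
) -> SegmentationMask:
    """Whole-voxel mask: face-connected voxels ≥ ``fraction`` × local max."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    peak = hill_climb(image, seed)
    peak_val = image.values[peak]
    if peak_val <= 0:
        raise EmptySegmentationError("seed lies in a zero-valued region")
    above = image.values >= fraction * peak_val
    labels, _ = ndimage.label(above, structure=FACE_STRUCTURE)
    component = labels == labels[peak]
    return SegmentationMask(
        grid=image.grid,
        weights=component.astype(float),
        method="fixed_threshold",
        seed=seed,
        parameters={"fraction": fraction, "local_max_voxel": peak},
    )


# ---------------------------------------------------------------------------
# Gradient (inflection-point) segmentation
# ---------------------------------------------------------------------------


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)


def _profile_values(image: ActivityImage, center_mm, dirs, radii_mm) -> np.ndarray:
    """Cubic-spline samples along each ray: (n_rays, n_steps).

    Cubic interpolation gives C² profiles; trilinear profiles are piecewise
    linear and their chord slopes bias the detected inflection inward.
    """
    pts = center_mm[None, None, :] + dirs[:, None, :] * radii_mm[None, :, None]
    idx = image.grid.world_to_index(pts.reshape(-1, 3)).T
    vals = ndimage.map_coordinates(image.values, idx, order=3, mode="nearest")
    return vals.reshape(dirs.shape[0], radii_mm.size)


# -- curvature compensation -------------------------------------------------
#
# For a uniform ball of radius R imaged at Gaussian resolution σ, the radial
# inflection point sits inside the true boundary (≈ R − σ²/R for R ≳ 2σ).
# Knowing the working resolution we can invert the forward map R ↦ r*(R)
# computed from the analytic blurred-ball profile, recovering the boundary of
# a locally sphere-like lesion without bias.


def _blurred_ball_profile(r: np.ndarray, R: float, sigma: float) -> np.ndarray:
    from scipy.special import erf

    r = np.maximum(r, 1e-9)
    s2 = sigma * math.sqrt(2.0)
    a = 0.5 * (erf((R - r) / s2) + erf((R + r) / s2))
    b = sigma / (r * math.sqrt(2.0 * math.pi)) * (
        np.exp(-((r - R) ** 2) / (2.0 * sigma**2))
        - np.exp(-((r + R) ** 2) / (2.0 * sigma**2))
    )
    return a - b


_INFLECTION_MAP_CACHE: dict = {}


def _inflection_map(sigma: float):
    """Monotone table R ↦ r*(R) of inflection radii, cached per σ."""
    key = round(sigma, 4)
    if key in _INFLECTION_MAP_CACHE:
        return _INFLECTION_MAP_CACHE[key]
    R_grid = sigma * np.linspace(0.4, 15.0, 300)
    r_star = np.empty_like(R_grid)
    for i, R in enumerate(R_grid):
        r = np.linspace(sigma / 100.0, R + 6.0 * sigma, 4000)
        d1 = np.gradient(_blurred_ball_profile(r, R, sigma), r)
        k = int(np.argmin(d1))
        r_star[i] = r[k]
    # enforce monotonicity for a well-defined inverse
    r_star = np.maximum.accumulate(r_star)
    _INFLECTION_MAP_CACHE[key] = (r_star, R_grid)
    return _INFLECTION_MAP_CACHE[key]


def _curvature_correct(radii: np.ndarray, sigma: float) -> np.ndarray:
    """Map measured inflection radii to ball radii at resolution σ."""
    if sigma <= 0:
        return radii
    r_star, R_grid = _inflection_map(sigma)
    return np.interp(radii, r_star, R_grid)


def _refine_center(image: ActivityImage, peak, half_width: int = 2, n_iter: int = 2) -> np.ndarray:
    """Sub-voxel profile origin: centroid of the ≥ 50 %-of-peak core.

    The hottest voxel can sit a couple of mm off the lesion centroid (noise,
    Gibbs ringing, discretization); radii measured from an off-centre origin
    systematically shorten oblique chords, so the origin is re-centred on the
    background-suppressed core before rays are cast.
    """
    idx = np.asarray(peak)
    shape = np.asarray(image.values.shape)
    for _ in range(n_iter):
        lo = np.maximum(idx - half_width, 0)
        hi = np.minimum(idx + half_width + 1, shape)
        patch = image.values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        w = np.maximum(patch - 0.5 * patch.max(), 0.0)
        if w.sum() == 0:
            break
        grids = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij")
        frac_idx = np.array([float((w * gax).sum() / w.sum()) for gax in grids])
        new_idx = np.rint(frac_idx).astype(int)
        if np.all(new_idx == idx):
            idx_frac = frac_idx
            break
        idx = new_idx
        idx_frac = frac_idx
    return np.asarray(image.grid.index_to_world(idx_frac), dtype=float)


def _competing_max_clip(image: ActivityImage, center_mm, default_radius: float) -> float:
    """Half the distance to the nearest competing local maximum, capped at
    ``default_radius``.

    A competitor must stand clearly above background (> 2× the median) AND be
    comparable to the lesion's own peak (≥ 30 %), so noise spikes in the
    background or inside the lesion's own spill-out do not truncate profiles.
    """
    vals = image.values
    bkg = float(np.median(vals))
    own_peak = float(
        vals[tuple(np.clip(np.rint(image.grid.world_to_index(center_mm)).astype(int),
                           0, np.asarray(vals.shape) - 1))]
    )
    footprint = np.ones((3, 3, 3), bool)
    is_max = (
        (vals == ndimage.maximum_filter(vals, footprint=footprint))
        & (vals > 2.0 * bkg)
        & (vals >= 0.3 * own_peak)
    )
    coords = np.argwhere(is_max)
    if coords.size == 0:
        return default_radius
    world = image.grid.index_to_world(coords)
    dist = np.linalg.norm(world - center_mm, axis=1)
    keep = dist > max(image.grid.spacing) * 2.0  # exclude the lesion's own max
    clip = default_radius
    for cand, d in zip(world[keep], dist[keep]):
        if d / 2.0 >= clip:
            continue
        # same-basin test: only a maximum separated by a clear valley competes
        ts = np.linspace(0.0, 1.0, 16)[1:-1]
        seg = center_mm[None, :] * (1 - ts[:, None]) + cand[None, :] * ts[:, None]
        idx = image.grid.world_to_index(seg).T
        valley = float(ndimage.map_coordinates(vals, idx, order=1, mode="nearest").min())
        cand_val = float(ndimage.map_coordinates(vals, image.grid.world_to_index(cand)[:, None], order=1, mode="nearest")[0])
        if valley < 0.6 * min(own_peak, cand_val):
            clip = d / 2.0
    return clip


def _ray_boundary(profile: np.ndarray, step: float) -> float | None:
    """Boundary distance along one smoothed profile, or None if no inflection."""
    d1 = np.gradient(profile, step)
    d2 = np.gradient(d1, step)
    k0 = int(np.argmin(d1))
    if d1[k0] >= 0:  # profile never descends
        return None
    start = max(k0 - 1, 0)
    for k in range(start, len(d2) - 1):
        if d2[k] <= 0.0 < d2[k + 1]:
            frac = -d2[k] / (d2[k + 1] - d2[k]) if d2[k + 1] != d2[k] else 0.0
            return (k + frac) * step
    return None


def segment_gradient(
    image: ActivityImage,
    seed: SeedPoint,
    n_rays: int = 64,
    step: float | None = None,
    max_radius: float | None = None,
    profile_sigma_steps: float = 1.0,
    ray_smooth_deg: float = 20.0,
    resolution_fwhm: float = 4.7,
) -> SegmentationMask:
    """Sub-voxel gradient segmentation by radial inflection detection.

    Parameters
    ----------
    n_rays : int
        Number of spherical-Fibonacci profile directions.
    step : float, optional
        Radial sampling step in mm; defaults to ¼ of the minimum voxel spacing.
    max_radius : float, optional
        Profile search limit in mm; defaults to 40 mm, shortened to half the
        distance to the nearest competing local maximum.
    resolution_fwhm : float
        Working image resolution (mm FWHM) used to compensate the inward
        curvature bias of the inflection point on sphere-like lesions
        (voxel-sampling blur is added automatically); 0 disables the
        compensation and returns the raw inflection surface.
    """
    if step is None:
        step = min(image.grid.spacing) / 4.0
    peak = hill_climb(image, seed)
    if image.values[peak] <= 0:
        raise EmptySegmentationError("seed lies in a zero-valued region")
    center_mm = _refine_center(image, peak)

    if max_radius is None:
        max_radius = _competing_max_clip(image, center_mm, 40.0)
    n_steps = max(int(math.ceil(max_radius / step)) + 1, 8)
    radii_mm = np.arange(n_steps) * step

    dirs = _fibonacci_directions(n_rays)
    profiles = _profile_values(image, center_mm, dirs, radii_mm)
    profiles = ndimage.gaussian_filter1d(profiles, profile_sigma_steps, axis=1, mode="nearest")

    boundaries = np.array(
        [
            b if (b := _ray_boundary(profiles[r], step)) is not None else np.nan
            for r in range(n_rays)
        ]
    )
    found = ~np.isnan(boundaries)
    if not found.any():
        raise NoBoundaryError(
            f"no second-derivative zero-crossing within {max_radius:.1f} mm on any ray"
        )
    # fill failed rays from their neighbours before smoothing
    if not found.all():
        boundaries[~found] = np.interp(
            np.flatnonzero(~found), np.flatnonzero(found), boundaries[found]
        )

    # smooth the radial boundary function over neighbouring directions
    sigma_rad = math.radians(ray_smooth_deg)
    cosang = np.clip(dirs @ dirs.T, -1.0, 1.0)
    ang = np.arccos(cosang)
    kernel = np.exp(-0.5 * (ang / sigma_rad) ** 2)
    radii_smooth = (kernel @ boundaries) / kernel.sum(axis=1)

    if resolution_fwhm > 0:
        sigma_psf = resolution_fwhm / 2.3548
        sigma_vox2 = float(np.mean(np.square(image.grid.spacing))) / 12.0
        sigma_eff = math.sqrt(sigma_psf**2 + sigma_vox2)
        radii_smooth = _curvature_correct(radii_smooth, sigma_eff)

    weights = _star_convex_weights(image.grid, center_mm, dirs, radii_smooth)
    return SegmentationMask(
        grid=image.grid,
        weights=weights,
        method="gradient",
        seed=seed,
        parameters={
            "n_rays": n_rays,
            "step": step,
            "max_radius": max_radius,
            "local_max_voxel": peak,
        },
    )


def _star_convex_weights(
    grid: VoxelGrid, center_mm: np.ndarray, dirs: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Fractional voxel weights of the star-convex region {|p−c| ≤ r(dir(p))}.

    Sub-voxel points interpolate the boundary radius from the nearest ray
    directions (Gaussian weights on angular distance); the same fixed-order
    supersampler as the phantom rasterizer decides inclusion.
    """
    rmax = float(radii.max())
    lo = np.maximum(np.floor(grid.world_to_index(center_mm - rmax) - 0.5).astype(int), 0)
    hi = np.minimum(
        np.ceil(grid.world_to_index(center_mm + rmax) + 0.5).astype(int),
        np.asarray(grid.shape),
    )
    weights = np.zeros(grid.shape, dtype=float)
    if np.any(lo >= hi):
        return weights

    off = _subcell_offsets(SUPERSAMPLE)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    axes = [
        ((np.arange(lo[d], hi[d])[:, None] + off[None, :]) * spacing[d] + origin[d]).ravel()
        for d in range(3)
    ]
    box_shape = tuple(hi - lo)
    px = axes[0][:, None, None]
    py = axes[1][None, :, None]
    pz = axes[2][None, None, :]
    dx = px - center_mm[0]
    dy = py - center_mm[1]
    dz = pz - center_mm[2]
    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
    dist_safe = np.where(dist == 0, 1.0, dist)
    pts = np.stack(
        [
            np.broadcast_to(dx, dist.shape) / dist_safe,
            np.broadcast_to(dy, dist.shape) / dist_safe,
            np.broadcast_to(dz, dist.shape) / dist_safe,
        ],
        axis=-1,
    ).reshape(-1, 3)
    # interpolate r(direction): Gaussian kernel over ray directions
    cosang = np.clip(pts @ dirs.T, -1.0, 1.0)
    ang = np.arccos(cosang)
    kern = np.exp(-0.5 * (ang / math.radians(25.0)) ** 2) + 1e-12
    r_here = (kern @ radii) / kern.sum(axis=1)
    inside = (dist.ravel() <= r_here) | (dist.ravel() == 0)
    inside = inside.reshape(dist.shape)

    n = SUPERSAMPLE
    sub = inside.reshape(
        box_shape[0], n, box_shape[1], n, box_shape[2], n
    ).mean(axis=(1, 3, 5))
    weights[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = sub
    return weights
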