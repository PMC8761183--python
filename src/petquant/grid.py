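"""Voxel grids and the world ↔ index coordinate mapping.

World coordinates are in millimetres; voxel indices are 0-based and values
are samples at voxel centres.  ``origin`` is the world coordinate of the
centre of voxel (0, 0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default voxel spacing (mm).  Chosen so one voxel is ~0.0433 mL, i.e. six
#: voxels enclose 0.26 mL — the apex ROI convention used throughout.
DEFAULT_SPACING = (3.65, 3.65, 3.27)


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel grid with physical spacing.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each axis.
    spacing : tuple of float
        Voxel edge lengths in mm.
    origin : tuple of float
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(n <= 0 for n in shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mL (= cm³; spacings are mm)."""
        sx, sy, sz = self.spacing
        return sx * sy * sz / 1000.0

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid along each axis (mm)."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def index_to_world(self, index) -> np.ndarray:
        """World coordinate (mm) of voxel centre(s); ``index`` may be fractional."""
        idx = np.asarray(index, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, world) -> np.ndarray:
        """Continuous (fractional) voxel index of world coordinate(s)."""
        w = np.asarray(world, dtype=float)
        return (w - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_to_nearest_voxel(self, world) -> tuple[int, int, int]:
        idx = np.rint(self.world_to_index(world)).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise ValueError(f"world coordinate {world} outside grid")
        return tuple(int(i) for i in idx)

    def contains_world(self, world) -> bool:
        """True if the point falls within the outer voxel faces of the grid."""
        idx = self.world_to_index(world)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.asarray(self.shape) - 0.5))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij-indexed) of voxel-centre world coordinates."""
        axes = [
            np.arange(n) * s + o
            for n, s, o in zip(self.shape, self.spacing, self.origin)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def centered(shape, spacing=DEFAULT_SPACING) -> "VoxelGrid":
        """Grid whose world origin sits at the geometric centre of the volume."""
        shape = tuple(int(n) for n in shape)
        origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
        return VoxelGrid(shape=shape, spacing=tuple(spacing), origin=origin)

    centered = staticmethod(centered)


@dataclass
class ActivityImage:
    """A 3-D field of activity concentration (kBq/mL) on a :class:`VoxelGrid`.

    ``timestamp`` is the acquisition time in minutes relative to the phantom's
    reference time.
    """

    grid: VoxelGrid
    values: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("activity concentrations must be non-negative")

    @property
    def total_activity(self) -> float:
        """Total activity in kBq (Σ values × voxel volume)."""
        return float(self.values.sum() * self.grid.voxel_volume)

    def copy_with(self, values: np.ndarray, timestamp: float | None = None) -> "ActivityImage":
        return ActivityImage(
            grid=self.grid,
            values=values,
            timestamp=self.timestamp if timestamp is None else timestamp,
        )
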