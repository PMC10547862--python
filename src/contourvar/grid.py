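"""Voxel-grid data model shared by every stage of the analysis.

All world coordinates are in millimetres. Voxel indices are 0-based and the
world position of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``
(voxel-centre convention). Volumes are reported in cm^3 = count * voxel
volume (mm^3) / 1000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "ObserverCohort",
    "CohortConsistencyError",
    "GRID_TOL_MM",
]

#: tolerance used when deciding whether two grids are the same lattice;
#: absorbs header rounding noise in co-registered cohorts
GRID_TOL_MM = 1e-3


class CohortConsistencyError(ValueError):
    """Raised when masks claimed to be co-registered live on different grids."""


@dataclass(frozen=True)
class VolumeGrid:
    """A regular anisotropic voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z); every entry >= 1.
    spacing : tuple of float
        Voxel size in mm along each axis; every entry > 0.
    origin : tuple of float
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("grid shape, spacing and origin must be length-3")
        if any(s < 1 for s in shape):
            raise ValueError(f"grid shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"grid spacing entries must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def index_coordinates(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world-mm points (inverse of above)."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinate vectors (mm)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )

    def matches(self, other: "VolumeGrid", tol_mm: float = GRID_TOL_MM) -> bool:
        """Same lattice as ``other`` up to ``tol_mm`` of header rounding."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol_mm, rtol=0)
            and np.allclose(self.origin, other.origin, atol=tol_mm, rtol=0)
        )

    def require_match(self, other: "VolumeGrid", context: str = "mask") -> None:
        if not self.matches(other):
            raise CohortConsistencyError(
                f"{context} grid mismatch: {other} does not match expected {self}"
            )


@dataclass
class BinaryMask:
    """One observer's delineation as a boolean field on a :class:`VolumeGrid`.

    Connectivity is not required: an observer may delineate disconnected
    regions, and empty masks are legal input (flagged downstream).
    """

    grid: VolumeGrid
    voxels: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.shape != self.grid.shape:
            raise ValueError(
                f"voxel array shape {vox.shape} does not match grid {self.grid.shape}"
            )
        self.voxels = vox.astype(bool)

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_cm3(self) -> float:
        return self.count * self.grid.voxel_volume_mm3 / 1000.0

    def centroid_mm(self) -> np.ndarray:
        """Centroid of the inside voxel centres, in mm."""
        if self.count == 0:
            raise ValueError(f"mask {self.label!r} is empty; centroid undefined")
        idx = np.argwhere(self.voxels)
        return self.grid.world_coordinates(idx.mean(axis=0))


@dataclass
class ObserverCohort:
    """An ordered set of co-registered observer masks for one case.

    Every mask must share the identical grid (within :data:`GRID_TOL_MM`);
    observer labels must be unique.
    """

    grid: VolumeGrid
    masks: list[BinaryMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.masks) < 2:
            raise ValueError(
                f"a cohort needs at least 2 observers, got {len(self.masks)}"
            )
        for i, m in enumerate(self.masks):
            self.grid.require_match(m.grid, context=f"observer {i} ({m.label!r})")
            if not m.label:
                m.label = f"obs{i + 1:02d}"
        labels = [m.label for m in self.masks]
        if len(set(labels)) != len(labels):
            raise ValueError(f"observer labels are not unique: {labels}")
        empties = [m.label for m in self.masks if m.count == 0]
        if empties:
            warnings.warn(
                f"cohort contains empty observer masks: {empties}", stacklevel=2
            )

    @property
    def n_observers(self) -> int:
        return len(self.masks)

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.masks]

    def stacked(self) -> np.ndarray:
        """All masks as one (n_observers, nx, ny, nz) boolean array."""
        return np.stack([m.voxels for m in self.masks], axis=0)
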