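"""Shared fixtures: grids, voxelised spheres, random blobby cohorts."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from contourvar import BinaryMask, ObserverCohort, VolumeGrid


def voxel_sphere(
    grid: VolumeGrid, center_mm, radius_mm: float, label: str = ""
) -> BinaryMask:
    """Direct centre-inclusion sphere, independent of the phantom module."""
    xs, ys, zs = grid.voxel_centers()
    gx, gy, gz = np.meshgrid(
        xs - center_mm[0], ys - center_mm[1], zs - center_mm[2], indexing="ij"
    )
    return BinaryMask(
        grid=grid,
        voxels=gx**2 + gy**2 + gz**2 <= radius_mm**2,
        label=label or f"sphere-r{radius_mm:g}",
    )


def random_blob_mask(
    grid: VolumeGrid, rng: np.random.Generator, label: str = "", smooth: float = 2.5
) -> BinaryMask:
    """Random smooth blobby mask: thresholded filtered noise, never empty."""
    field = gaussian_filter(rng.standard_normal(grid.shape), smooth)
    mask = field > np.quantile(field, 0.85)
    if not mask.any():  # pragma: no cover - quantile guarantees nonempty
        mask[tuple(s // 2 for s in grid.shape)] = True
    return BinaryMask(grid=grid, voxels=mask, label=label)


def random_cohort(
    grid: VolumeGrid, n_observers: int, rng: np.random.Generator
) -> ObserverCohort:
    masks = [
        random_blob_mask(grid, rng, label=f"obs{i + 1:02d}")
        for i in range(n_observers)
    ]
    return ObserverCohort(grid=grid, masks=masks)


@pytest.fixture
def grid32() -> VolumeGrid:
    return VolumeGrid(shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def grid64() -> VolumeGrid:
    return VolumeGrid(shape=(64, 64, 64), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def aniso_grid() -> VolumeGrid:
    return VolumeGrid(shape=(48, 48, 40), spacing=(1.0, 1.0, 1.5), origin=(2.0, -3.0, 5.0))
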