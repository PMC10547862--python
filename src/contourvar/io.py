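"""Mask, polygon and report I/O.

Masks are exchanged as NIfTI volumes (nonzero = inside), one file per
observer. Slice-wise delineations can be supplied as a simple JSON polygon
interchange format and are rasterised to masks on ingest — masks are the
canonical representation because all statistics downstream are voxel based.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import matplotlib.path as mpath
import nibabel as nib
import numpy as np
from shapely.geometry import LineString

from .grid import BinaryMask, CohortConsistencyError, VolumeGrid

__all__ = [
    "read_mask",
    "write_mask",
    "polygons_to_mask",
    "read_polygon_json",
    "write_polygon_json",
    "MaskFormatError",
]

# Rasterisation uses a half-open tie rule: a voxel centre exactly on the
# polygon boundary counts as inside on the low-x/low-y edges only, so
# abutting polygons never double-claim a voxel. Realised by nudging query
# points by +POLYGON_EDGE_EPS_MM before the point-in-polygon test.
POLYGON_EDGE_EPS_MM = 1e-9


class MaskFormatError(ValueError):
    """A volume file whose content cannot be interpreted as a 3D binary mask."""


def _grid_from_nifti(img: nib.Nifti1Image) -> VolumeGrid:
    affine = img.affine
    rot = affine[:3, :3]
    spacing = np.sqrt((rot**2).sum(axis=0))
    # only axis-aligned, positively oriented volumes are supported: the
    # cohort statistics assume one shared, axis-aligned lattice
    if not np.allclose(rot, np.diag(spacing), atol=1e-4):
        raise MaskFormatError(
            "only axis-aligned NIfTI volumes with positive orientation are "
            f"supported; affine rotation block is {rot.tolist()}"
        )
    return VolumeGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in affine[:3, 3]),
    )


def read_mask(
    path: str | Path,
    expected_grid: VolumeGrid | None = None,
    label: str = "",
) -> BinaryMask:
    """Read a NIfTI volume as a binary mask (nonzero = inside).

    Parameters
    ----------
    path : path
        A ``.nii`` / ``.nii.gz`` file containing a 3D volume.
    expected_grid : VolumeGrid, optional
        If given, the file's grid must match it (shape exactly; spacing and
        origin within 1e-3 mm) or a :class:`CohortConsistencyError` is raised.
    label : str
        Observer identifier; defaults to the file stem.
    """
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated types
        raise OSError(f"cannot read mask volume {path}: {exc}") from exc
    if img.ndim != 3:
        raise MaskFormatError(f"{path}: expected a 3D volume, got {img.ndim}D")
    data = np.asanyarray(img.dataobj)
    if not np.isfinite(data).all():
        raise MaskFormatError(f"{path}: volume contains non-finite values")
    grid = _grid_from_nifti(img)
    if expected_grid is not None:
        try:
            expected_grid.require_match(grid, context=str(path))
        except CohortConsistencyError:
            raise
    return BinaryMask(grid=grid, voxels=data != 0, label=label or path.stem)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI with a diagonal affine from its grid."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(mask.grid.spacing)
    affine[:3, 3] = mask.grid.origin
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    nib.save(img, str(path))


def polygons_to_mask(
    slices: list[tuple[int, np.ndarray]],
    grid: VolumeGrid,
    label: str = "",
) -> BinaryMask:
    """Rasterise per-slice closed polygons (mm coordinates) to a mask.

    A voxel is included iff its centre lies inside the polygon of its slice
    (even-odd rule, half-open on boundary ties); slices without polygons are
    empty. Multiple polygons on one slice combine by even-odd parity, so a
    polygon inside another cuts a hole.

    Parameters
    ----------
    slices : list of (z_index, (n, 2) array)
        Closed simple polygons; the first and last vertex may but need not
        coincide.
    """
    voxels = np.zeros(grid.shape, dtype=bool)
    xs, ys, _ = grid.voxel_centers()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()]) + POLYGON_EDGE_EPS_MM
    for z, poly in slices:
        z = int(z)
        if not 0 <= z < grid.shape[2]:
            raise ValueError(f"slice index {z} outside grid nz={grid.shape[2]}")
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValueError("each polygon must be an (n >= 3, 2) array")
        ring = poly if np.allclose(poly[0], poly[-1]) else np.vstack([poly, poly[0]])
        if not LineString(ring).is_simple:
            raise ValueError(f"polygon on slice {z} is self-intersecting")
        path = mpath.Path(ring, closed=True)
        inside = path.contains_points(pts).reshape(grid.shape[:2])
        voxels[:, :, z] ^= inside  # even-odd across multiple polygons
    return BinaryMask(grid=grid, voxels=voxels, label=label)


def _grid_to_dict(grid: VolumeGrid) -> dict:
    return {
        "shape": list(grid.shape),
        "spacing_mm": list(grid.spacing),
        "origin_mm": list(grid.origin),
    }


def _grid_from_dict(d: dict) -> VolumeGrid:
    return VolumeGrid(
        shape=tuple(d["shape"]),
        spacing=tuple(d["spacing_mm"]),
        origin=tuple(d["origin_mm"]),
    )


def write_polygon_json(
    slices: list[tuple[int, np.ndarray]], grid: VolumeGrid, path: str | Path
) -> None:
    doc = {
        "grid": _grid_to_dict(grid),
        "slices": [
            {"z": int(z), "xy_mm": np.asarray(p, dtype=float).tolist()}
            for z, p in slices
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_polygon_json(path: str | Path, label: str = "") -> BinaryMask:
    """Read the polygon interchange JSON and rasterise it."""
    doc = json.loads(Path(path).read_text())
    grid = _grid_from_dict(doc["grid"])
    slices = [(s["z"], np.asarray(s["xy_mm"], dtype=float)) for s in doc["slices"]]
    if not slices:
        warnings.warn(f"{path}: no slices; returning empty mask", stacklevel=2)
    return polygons_to_mask(slices, grid, label=label or Path(path).stem)
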