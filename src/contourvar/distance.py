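"""Perpendicular-distance variation from the median surface to each observer.

For every evaluation point on the median surface, the signed distance to
each observer's contour surface is computed (positive outside the
observer's mask, negative inside), the magnitude clipped at 20 mm, and the
per-point standard deviation taken across observers. The overall statistic
is the root of the mean squared per-point SD, reported in cm (RMS-SD).

"Perpendicular distance" is implemented as the nearest Euclidean distance
to the observer surface, signed by inside/outside. The observer surface is
the sub-voxel 0.5-isosurface of the binary mask (the same surface
definition the median structure uses); magnitudes are nearest distances to
that surface, which avoids the half-voxel bias a centre-to-centre distance
transform carries near the boundary. A ray-cast variant along the
median-surface normal is available via ``distance_mode="normal-ray"`` for
sensitivity analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.ndimage import distance_transform_edt, map_coordinates
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .grid import BinaryMask, ObserverCohort
from .median import ISO_LEVEL, MedianStructure, surface_points

__all__ = [
    "DistanceField",
    "signed_distance_volume",
    "signed_distance",
    "compute_distance_field",
    "sd_map_export",
    "read_sd_map",
    "CLIP_MM",
    "SD_COLOR_SCALE_CM",
]

#: clipping limit: distance magnitudes larger than this are set to it
CLIP_MM = 20.0

#: colour scale used when the local SD map is rendered (cm): dark blue at
#: the low end to red at the high end
SD_COLOR_SCALE_CM = (0.1, 1.5)


def signed_distance_volume(mask: BinaryMask) -> np.ndarray:
    """Signed Euclidean distance (mm) to the mask surface, per voxel centre.

    Positive outside, negative inside. The zero level, interpolated between
    voxel centres, lies midway between inside and outside voxels — the same
    sub-voxel surface the 0.5-isosurface of the binary field defines.
    """
    vox = mask.voxels
    sp = mask.grid.spacing
    if not vox.any():
        raise ValueError(f"mask {mask.label!r} is empty; no surface exists")
    if vox.all():
        # no outside voxels: everything is maximally inside
        return np.full(vox.shape, -CLIP_MM)
    d_out = distance_transform_edt(~vox, sampling=sp)
    d_in = distance_transform_edt(vox, sampling=sp)
    return d_out - d_in


def _sample(volume: np.ndarray, idx_pts: np.ndarray) -> np.ndarray:
    return map_coordinates(volume, idx_pts.T, order=1, mode="nearest")


def mask_surface_vertices(mask: BinaryMask) -> np.ndarray:
    """Vertices (mm) of the mask's sub-voxel surface, padded so it is closed.

    Uses the same isosurface level as the median-structure extraction, so a
    mask compared against an identical mask has distance exactly zero.
    """
    padded = np.pad(mask.voxels.astype(np.float64), 1)
    verts, _, _, _ = marching_cubes(padded, level=ISO_LEVEL)
    return mask.grid.world_coordinates(verts - 1.0)


def signed_distance(
    points_mm: np.ndarray,
    observer: BinaryMask,
    clip_mm: float = CLIP_MM,
    normals: np.ndarray | None = None,
    distance_mode: str = "nearest",
) -> np.ndarray:
    """Clipped signed distances (mm) from query points to an observer surface.

    Parameters
    ----------
    points_mm : (n, 3) array
        Query points in world mm (typically median-surface vertices).
    observer : BinaryMask
    clip_mm : float
        Magnitudes above this are set to it, sign preserved.
    normals : (n, 3) array, optional
        Outward unit normals; required for ``distance_mode="normal-ray"``.
    distance_mode : {"nearest", "normal-ray"}

    An empty observer mask yields +clip_mm everywhere (maximal
    disagreement) with a warning.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    if observer.count == 0:
        warnings.warn(
            f"observer {observer.label!r} has an empty mask: all distances "
            f"set to +{clip_mm:g} mm",
            stacklevel=2,
        )
        return np.full(len(pts), clip_mm)
    if distance_mode == "nearest":
        magnitude = cKDTree(mask_surface_vertices(observer)).query(pts)[0]
        # outside the grid counts as outside the mask (cval=0)
        inside = (
            map_coordinates(
                observer.voxels.astype(np.float64),
                observer.grid.index_coordinates(pts).T,
                order=1,
                mode="constant",
                cval=0.0,
            )
            > 0.5
        )
        d = np.where(inside, -magnitude, magnitude)
    elif distance_mode == "normal-ray":
        if normals is None:
            raise ValueError("normal-ray distance requires normals")
        sdv = signed_distance_volume(observer)
        d = _normal_ray_distance(pts, np.asarray(normals, float), observer, sdv, clip_mm)
    else:
        raise ValueError(f"unknown distance_mode {distance_mode!r}")
    return np.clip(d, -clip_mm, clip_mm)


def _normal_ray_distance(
    pts: np.ndarray,
    normals: np.ndarray,
    observer: BinaryMask,
    sdv: np.ndarray,
    clip_mm: float,
) -> np.ndarray:
    """Distance along +/- the surface normal to the observer surface.

    Samples the signed-distance volume along each ray at quarter-voxel
    steps over [-clip, +clip], takes the sign change nearest the origin
    point and locates the crossing by linear interpolation of the sampled
    values (the interpolated field is piecewise linear along the ray, so
    the crossing is exact up to sampling straddle). Rays that never cross
    within the clip range are clipped, keeping the local inside/outside
    sign.
    """
    step = 0.25 * min(observer.grid.spacing)
    ts = np.arange(-clip_mm, clip_mm + step / 2, step)
    n_pts, n_t = len(pts), len(ts)
    samples = pts[:, None, :] + ts[None, :, None] * normals[:, None, :]
    f = _sample(sdv, observer.grid.index_coordinates(samples.reshape(-1, 3)))
    f = f.reshape(n_pts, n_t)
    f0 = _sample(sdv, observer.grid.index_coordinates(pts))
    crossing = np.signbit(f[:, :-1]) != np.signbit(f[:, 1:])
    mid_t = np.abs(0.5 * (ts[:-1] + ts[1:]))
    # nearest crossing to t = 0; rows without any crossing get a sentinel
    penal = np.where(crossing, mid_t[None, :], np.inf)
    j = np.argmin(penal, axis=1)
    has_crossing = np.isfinite(penal[np.arange(n_pts), j])
    fj = f[np.arange(n_pts), j]
    fj1 = f[np.arange(n_pts), j + 1]
    denom = fj1 - fj
    frac = np.where(denom != 0, -fj / np.where(denom != 0, denom, 1.0), 0.5)
    t_hit = ts[j] + frac * step
    sign = np.where(f0 < 0, -1.0, 1.0)
    out = np.where(has_crossing, sign * np.abs(t_hit), sign * clip_mm)
    return np.where(f0 == 0, 0.0, out)


@dataclass
class DistanceField:
    """Per-point clipped signed distances to every observer, and derived SDs."""

    points_mm: np.ndarray  # (np, 3)
    normals: np.ndarray  # (np, 3)
    point_indices: np.ndarray  # indices into the median-surface vertex list
    observer_labels: list[str]
    distances_mm: np.ndarray  # (np, n_observers), clipped
    local_sd_mm: np.ndarray  # (np,)
    rms_sd_cm: float
    clip_mm: float = CLIP_MM
    sd_ddof: int = 1
    area_weighted: bool = False
    sign_convention: str = "positive-outside"
    n_clipped: int = 0

    @property
    def local_sd_cm(self) -> np.ndarray:
        return self.local_sd_mm / 10.0

    def metadata(self) -> dict:
        """Everything needed to reproduce the statistic from the distances."""
        return {
            "sign_convention": self.sign_convention,
            "clip_mm": self.clip_mm,
            "sd_ddof": self.sd_ddof,
            "area_weighted_rms": self.area_weighted,
            "n_points": int(len(self.points_mm)),
            "n_observers": len(self.observer_labels),
            "n_clipped_distances": int(self.n_clipped),
            "color_scale_cm": list(SD_COLOR_SCALE_CM),
        }


def compute_distance_field(
    structure: MedianStructure,
    cohort: ObserverCohort,
    clip_mm: float = CLIP_MM,
    sd_ddof: int = 1,
    area_weighted: bool = False,
    distance_mode: str = "nearest",
    max_points: int | None = None,
    seed: int = 0,
) -> DistanceField:
    """Distances from the median surface to every observer, with SD map.

    ``local_sd`` is the SD of the clipped distances across observers at
    each point, with denominator ``n_observers - sd_ddof`` (sample SD by
    default); ``rms_sd_cm = sqrt(mean_p local_sd(p)^2) / 10``. With
    ``area_weighted`` the mean over points uses per-vertex area weights to
    compensate for nonuniform mesh vertex density.
    """
    if cohort.n_observers < 2:
        raise ValueError("SD over observers needs at least 2 observers")
    if structure.is_empty or structure.surface.n_vertices == 0:
        raise ValueError("median surface is empty; distance field undefined")
    pts, normals, idx = surface_points(structure, max_points=max_points, seed=seed)
    dist = np.empty((len(pts), cohort.n_observers))
    for o, mask in enumerate(cohort.masks):
        dist[:, o] = signed_distance(
            pts, mask, clip_mm=clip_mm, normals=normals, distance_mode=distance_mode
        )
    n_clipped = int((np.abs(dist) >= clip_mm).sum())
    local_sd = dist.std(axis=1, ddof=sd_ddof)
    if area_weighted:
        w = structure.surface.vertex_areas()[idx]
        w = w / w.sum()
        rms_mm = float(np.sqrt(np.sum(w * local_sd**2)))
    else:
        rms_mm = float(np.sqrt(np.mean(local_sd**2)))
    return DistanceField(
        points_mm=pts,
        normals=normals,
        point_indices=idx,
        observer_labels=cohort.labels,
        distances_mm=dist,
        local_sd_mm=local_sd,
        rms_sd_cm=rms_mm / 10.0,
        clip_mm=clip_mm,
        sd_ddof=sd_ddof,
        area_weighted=area_weighted,
        n_clipped=n_clipped,
    )


def sd_map_export(
    field: DistanceField,
    structure: MedianStructure,
    path: str | Path,
    color_scale_cm: tuple[float, float] = SD_COLOR_SCALE_CM,
) -> None:
    """Write the median surface with per-vertex local SD (cm) attached.

    The format follows the file suffix: ``.ply`` (float vertex property
    ``local_sd_cm``) or ``.vtk`` (legacy polydata with a point-scalar
    channel). A JSON sidecar (``<path>.<ext>.json``) records the sign
    convention, clip limit, SD denominator, weighting flag and the colour
    scale, so any reported RMS-SD is reproducible from the file pair.
    """
    mesh = structure.surface
    if len(field.point_indices) != mesh.n_vertices or not np.array_equal(
        field.point_indices, np.arange(mesh.n_vertices)
    ):
        raise ValueError(
            "distance field was computed on a vertex subsample; the SD map "
            "export needs the full vertex set (max_points=None)"
        )
    path = Path(path)
    if path.suffix == ".vtk":
        from .vtkio import write_vtk_polydata

        write_vtk_polydata(
            mesh.vertices,
            mesh.faces,
            path,
            point_scalars={"local_sd_cm": field.local_sd_cm},
        )
    else:
        tm = trimesh.Trimesh(
            vertices=mesh.vertices,
            faces=mesh.faces,
            vertex_normals=mesh.normals,
            process=False,
        )
        tm.vertex_attributes["local_sd_cm"] = field.local_sd_cm.astype(np.float32)
        tm.export(path, encoding="ascii")
    sidecar = field.metadata()
    sidecar["color_scale_cm"] = list(color_scale_cm)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_sd_map(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read back an SD map: (vertices mm, local SD cm, sidecar metadata)."""
    path = Path(path)
    tm = trimesh.load(path, process=False)
    raw = tm.metadata["_ply_raw"]["vertex"]["data"]
    sd = np.asarray(raw["local_sd_cm"], dtype=float).ravel()
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return np.asarray(tm.vertices), sd, meta
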