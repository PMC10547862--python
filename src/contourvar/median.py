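"""Observer-coverage map and median (>= 50%-coverage) structure.

The coverage map holds, per voxel, the fraction of observers whose
delineation contains that voxel. The median structure is the set of voxels
delineated by at least 50% of the observers — with an even number of
observers, exactly half suffices — and its surface is extracted as the
0.5-level isosurface of the coverage fraction field (trilinear between
voxel centres), giving a sub-voxel consensus surface. The alternative,
extracting the boundary of the binarised majority-vote mask, is available
via ``surface_mode="mask-boundary"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.measure import marching_cubes

from .grid import BinaryMask, ObserverCohort, VolumeGrid

__all__ = [
    "CoverageMap",
    "SurfaceMesh",
    "MedianStructure",
    "compute_coverage",
    "extract_median_structure",
    "surface_points",
]

# The isosurface level sits just below 1/2 so that voxels with coverage
# exactly 1/2 (even cohorts) fall strictly inside, matching the ">= 50%"
# voxel rule. The same level defines every mask's sub-voxel surface, so a
# cohort of identical masks has distance exactly zero everywhere.
ISO_LEVEL = 0.5 - 1e-6


@dataclass(frozen=True)
class CoverageMap:
    """Per-voxel observer counts on a grid; fraction = counts / n_observers."""

    grid: VolumeGrid
    counts: np.ndarray
    n_observers: int

    @property
    def fraction(self) -> np.ndarray:
        return self.counts / self.n_observers

    def majority_mask(self) -> np.ndarray:
        # integer arithmetic: ties at exactly n/2 are inside (">= 50%")
        return 2 * self.counts >= self.n_observers


@dataclass
class SurfaceMesh:
    """Triangle mesh in world mm with outward unit normals per vertex."""

    vertices: np.ndarray  # (nv, 3) mm
    faces: np.ndarray  # (nf, 3) int
    normals: np.ndarray  # (nv, 3) unit, inside -> outside

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def vertex_areas(self) -> np.ndarray:
        """Per-vertex area weights: one third of each incident triangle."""
        v = self.vertices
        tri = v[self.faces]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        tri_area = 0.5 * np.linalg.norm(cross, axis=1)
        areas = np.zeros(len(v))
        for c in range(3):
            np.add.at(areas, self.faces[:, c], tri_area / 3.0)
        return areas


@dataclass
class MedianStructure:
    """The >= 50%-coverage mask, its surface mesh and voxel volume."""

    mask: BinaryMask
    surface: SurfaceMesh
    volume_cm3: float
    surface_mode: str = "coverage-isosurface"

    @property
    def is_empty(self) -> bool:
        return self.mask.count == 0


def compute_coverage(cohort: ObserverCohort) -> CoverageMap:
    """Count, per voxel, how many observers delineated it.

    Values of the derived fraction field are exactly k / n_observers.
    """
    counts = np.zeros(cohort.grid.shape, dtype=np.int32)
    for m in cohort.masks:
        counts += m.voxels
    return CoverageMap(grid=cohort.grid, counts=counts, n_observers=cohort.n_observers)


def _orient_normals_outward(
    verts_idx: np.ndarray, normals: np.ndarray, fraction: np.ndarray
) -> np.ndarray:
    """Flip normals so the coverage fraction decreases along them.

    Checked per vertex by trilinear sampling at +/- half a voxel along the
    normal in index space; vertices in flat-gradient spots inherit the
    majority orientation.
    """
    h = 0.5
    f_plus = map_coordinates(
        fraction, (verts_idx + h * normals).T, order=1, mode="nearest"
    )
    f_minus = map_coordinates(
        fraction, (verts_idx - h * normals).T, order=1, mode="nearest"
    )
    diff = f_plus - f_minus
    flip = diff > 0
    decided = np.abs(diff) > 1e-12
    if decided.any() and flip[decided].mean() > 0.5:
        undecided_flip = True
    else:
        undecided_flip = False
    flip = np.where(decided, flip, undecided_flip)
    out = normals.copy()
    out[flip] *= -1.0
    return out


def _extract_isosurface(
    fraction: np.ndarray, level: float, grid: VolumeGrid
) -> SurfaceMesh:
    import trimesh

    # pad with zeros so structures produce closed (watertight) surfaces even
    # when voxels touch the grid boundary
    padded = np.pad(fraction.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=level)
    verts_idx = verts - 1.0  # unpad, still in voxel-index units
    verts_mm = grid.world_coordinates(verts_idx)
    # normals from the mesh geometry (area-weighted incident faces); the
    # field-gradient normals marching cubes returns degenerate on coverage
    # plateaus (e.g. regions where exactly half the observers agree)
    tm = trimesh.Trimesh(vertices=verts_mm, faces=faces, process=False)
    n_mm = np.array(tm.vertex_normals, dtype=float)
    norms = np.linalg.norm(n_mm, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    n_mm = n_mm / norms
    # orientation: sampling direction back in index space (metric transform)
    sp = np.asarray(grid.spacing)
    n_idx = n_mm / sp
    n_idx /= np.linalg.norm(n_idx, axis=1, keepdims=True)
    n_oriented = _orient_normals_outward(verts_idx + 1.0, n_idx, padded)
    flipped = (n_oriented * n_idx).sum(axis=1) < 0
    n_mm[flipped] *= -1.0
    return SurfaceMesh(
        vertices=verts_mm,
        faces=faces.astype(np.int64),
        normals=n_mm,
    )


def extract_median_structure(
    coverage: CoverageMap, surface_mode: str = "coverage-isosurface"
) -> MedianStructure:
    """Extract the median structure and its triangulated surface.

    Parameters
    ----------
    coverage : CoverageMap
    surface_mode : {"coverage-isosurface", "mask-boundary"}
        Default takes the 0.5-isosurface of the fractional coverage field;
        the alternative meshes the boundary of the binarised majority mask
        (useful for sensitivity checks).
    """
    if surface_mode not in ("coverage-isosurface", "mask-boundary"):
        raise ValueError(f"unknown surface_mode {surface_mode!r}")
    vote = coverage.majority_mask()
    mask = BinaryMask(grid=coverage.grid, voxels=vote, label="median")
    volume_cm3 = mask.volume_cm3
    if mask.count == 0:
        warnings.warn(
            "median structure is empty (no voxel reaches 50% coverage)",
            stacklevel=2,
        )
        empty = SurfaceMesh(
            vertices=np.empty((0, 3)),
            faces=np.empty((0, 3), dtype=np.int64),
            normals=np.empty((0, 3)),
        )
        return MedianStructure(mask, empty, 0.0, surface_mode)
    if surface_mode == "coverage-isosurface":
        fld = coverage.fraction
    else:
        fld = vote.astype(np.float64)
    mesh = _extract_isosurface(fld, ISO_LEVEL, coverage.grid)
    return MedianStructure(mask, mesh, volume_cm3, surface_mode)


def surface_points(
    structure: MedianStructure,
    max_points: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluation points on the median surface: (vertices mm, normals, indices).

    With ``max_points`` given, a deterministic area-weighted subsample of
    the mesh vertices (probability proportional to incident triangle area)
    drawn with the given seed; otherwise all vertices in mesh order.
    """
    mesh = structure.surface
    if mesh.n_vertices == 0:
        warnings.warn("empty median surface: no evaluation points", stacklevel=2)
        return mesh.vertices, mesh.normals, np.empty(0, dtype=np.int64)
    if max_points is None or max_points >= mesh.n_vertices:
        idx = np.arange(mesh.n_vertices, dtype=np.int64)
    else:
        areas = mesh.vertex_areas()
        p = areas / areas.sum()
        rng = np.random.default_rng(seed)
        idx = np.sort(
            rng.choice(mesh.n_vertices, size=max_points, replace=False, p=p)
        )
    return mesh.vertices[idx], mesh.normals[idx], idx
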