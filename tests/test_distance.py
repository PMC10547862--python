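"""Signed surface distances, local SD map, RMS-SD, and the SD-map export."""

import json

import numpy as np
import pytest
from conftest import random_blob_mask, voxel_sphere

from contourvar import (
    BinaryMask,
    ObserverCohort,
    VolumeGrid,
    compute_coverage,
    compute_distance_field,
    extract_median_structure,
    read_sd_map,
    sd_map_export,
    signed_distance,
    surface_points,
)
from contourvar.distance import mask_surface_vertices


def boundary_face_midpoints(mask):
    """Independent oracle: midpoints of all faces between inside and outside
    voxels (including faces on the grid boundary), in mm."""
    v = mask.voxels
    sp = np.asarray(mask.grid.spacing)
    origin = np.asarray(mask.grid.origin)
    padded = np.pad(v, 1)
    mids = []
    for axis in range(3):
        diff = padded != np.roll(padded, -1, axis=axis)
        idx = np.argwhere(diff).astype(float)
        idx -= 1.0  # unpad
        idx[:, axis] += 0.5  # face sits midway to the next voxel centre
        mids.append(origin + idx * sp)
    return np.vstack(mids)


def _cohort_of(grid, *masks):
    return ObserverCohort(grid=grid, masks=list(masks))


class TestSignedDistance:
    def test_points_on_own_surface_are_near_zero(self, grid64):
        s = voxel_sphere(grid64, (31.5,) * 3, 10.0)
        pts = mask_surface_vertices(s)[::7]
        d = signed_distance(pts, s)
        assert np.all(np.abs(d) < 0.5 * np.sqrt(3.0))

    def test_concentric_spheres_signed_magnitude(self, grid64):
        """Median at r=10 inside an observer at r=12: distance ~ -2 mm."""
        center = (31.5,) * 3
        inner = voxel_sphere(grid64, center, 10.0, label="a")
        outer = voxel_sphere(grid64, center, 12.0, label="b")
        structure = extract_median_structure(
            compute_coverage(_cohort_of(grid64, inner, BinaryMask(
                grid=grid64, voxels=inner.voxels.copy(), label="a2")))
        )
        pts, _, _ = surface_points(structure)
        d = signed_distance(pts, outer)
        assert np.all(np.abs(d + 2.0) < 1.0)

    def test_far_displaced_observer_clips_exactly(self, grid64):
        near = voxel_sphere(grid64, (12.0, 31.5, 31.5), 6.0, label="n")
        far = voxel_sphere(grid64, (52.0, 31.5, 31.5), 6.0, label="f")
        pts = mask_surface_vertices(near)
        d = signed_distance(pts, far)
        assert np.all(np.abs(d) == 20.0)

    def test_empty_observer_is_maximal_disagreement(self, grid64):
        empty = BinaryMask(grid=grid64, voxels=np.zeros(grid64.shape, bool), label="e")
        with pytest.warns(UserWarning, match="empty"):
            d = signed_distance(np.array([[10.0, 10.0, 10.0]]), empty)
        assert d[0] == 20.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_boundary_face_oracle(self, seed):
        """Nearest signed distance vs brute-force min over boundary-face
        midpoints, within half a voxel diagonal."""
        grid = VolumeGrid(shape=(32, 32, 28), spacing=(1.0, 1.0, 1.2))
        rng = np.random.default_rng(seed)
        mask = random_blob_mask(grid, rng, label="m")
        faces = boundary_face_midpoints(mask)
        lo = np.asarray(grid.origin) - 2
        hi = np.asarray(grid.origin) + np.asarray(grid.shape) * grid.spacing + 2
        pts = rng.uniform(lo, hi, size=(60, 3))
        d = signed_distance(pts, mask, clip_mm=1e9)
        brute = np.min(
            np.linalg.norm(pts[:, None, :] - faces[None, :, :], axis=2), axis=1
        )
        half_diag = 0.5 * np.linalg.norm(grid.spacing)
        assert np.all(np.abs(np.abs(d) - brute) <= half_diag)
        # sign must match voxel membership of the containing voxel
        idx = np.round(grid.index_coordinates(pts)).astype(int)
        ok = np.all((idx >= 0) & (idx < grid.shape), axis=1)
        inside = np.zeros(len(pts), bool)
        inside[ok] = mask.voxels[tuple(idx[ok].T)]
        far_enough = brute > half_diag  # sign near the surface is ambiguous
        assert np.array_equal(d[far_enough] < 0, inside[far_enough])


class TestDistanceField:
    def test_zero_noise_rms_is_exactly_zero(self, grid64):
        s = voxel_sphere(grid64, (31.5,) * 3, 10.0)
        cohort = _cohort_of(
            grid64,
            *[
                BinaryMask(grid=grid64, voxels=s.voxels.copy(), label=f"o{i}")
                for i in range(4)
            ],
        )
        structure = extract_median_structure(compute_coverage(cohort))
        field = compute_distance_field(structure, cohort)
        assert field.rms_sd_cm == 0.0
        assert np.all(field.distances_mm == 0.0)

    def test_two_observer_closed_form(self, grid64):
        """Concentric spheres 9 and 11 mm: the median (union) surface sits on
        the outer sphere, distances are {~0, ~+2} mm, local SD ~ sqrt(2)."""
        center = (31.5,) * 3
        cohort = _cohort_of(
            grid64,
            voxel_sphere(grid64, center, 9.0, label="a"),
            voxel_sphere(grid64, center, 11.0, label="b"),
        )
        structure = extract_median_structure(compute_coverage(cohort))
        field = compute_distance_field(structure, cohort)
        assert np.all(np.abs(field.local_sd_mm - np.sqrt(2.0)) < 0.5)
        assert field.rms_sd_cm == pytest.approx(0.1414, abs=0.02)

    def test_symmetric_cohort_mean_signed_distance_near_zero(self, grid64):
        center = (31.5,) * 3
        cohort = _cohort_of(
            grid64,
            voxel_sphere(grid64, center, 9.0, label="a"),
            voxel_sphere(grid64, center, 10.0, label="b"),
            voxel_sphere(grid64, center, 11.0, label="c"),
        )
        structure = extract_median_structure(compute_coverage(cohort))
        field = compute_distance_field(structure, cohort)
        mean_per_point = field.distances_mm.mean(axis=1)
        assert np.all(np.abs(mean_per_point) < np.sqrt(3.0))

    def test_clipping_invariant_on_adversarial_cohort(self, grid64):
        near = voxel_sphere(grid64, (12.0, 31.5, 31.5), 6.0, label="n")
        near2 = voxel_sphere(grid64, (13.0, 31.5, 31.5), 6.0, label="n2")
        far = voxel_sphere(grid64, (52.0, 31.5, 31.5), 6.0, label="f")
        cohort = _cohort_of(grid64, near, near2, far)
        structure = extract_median_structure(compute_coverage(cohort))
        field = compute_distance_field(structure, cohort)
        assert np.max(np.abs(field.distances_mm)) <= 20.0
        assert field.n_clipped > 0

    def test_normal_ray_mode_on_concentric_spheres(self, grid64):
        center = (31.5,) * 3
        cohort = _cohort_of(
            grid64,
            voxel_sphere(grid64, center, 9.0, label="a"),
            voxel_sphere(grid64, center, 11.0, label="b"),
        )
        structure = extract_median_structure(compute_coverage(cohort))
        field = compute_distance_field(structure, cohort, distance_mode="normal-ray")
        assert field.rms_sd_cm == pytest.approx(0.1414, abs=0.025)

    def test_area_weighted_rms_close_to_unweighted_on_sphere(self, grid64):
        center = (31.5,) * 3
        cohort = _cohort_of(
            grid64,
            voxel_sphere(grid64, center, 9.0, label="a"),
            voxel_sphere(grid64, center, 11.0, label="b"),
        )
        structure = extract_median_structure(compute_coverage(cohort))
        fu = compute_distance_field(structure, cohort)
        fw = compute_distance_field(structure, cohort, area_weighted=True)
        assert fw.rms_sd_cm == pytest.approx(fu.rms_sd_cm, rel=0.05)

    def test_single_observer_rejected(self, grid64):
        s = voxel_sphere(grid64, (31.5,) * 3, 10.0)
        cohort = _cohort_of(
            grid64,
            s,
            BinaryMask(grid=grid64, voxels=s.voxels.copy(), label="b"),
        )
        structure = extract_median_structure(compute_coverage(cohort))

        class FakeCohort:
            n_observers = 1

        with pytest.raises(ValueError):
            compute_distance_field(structure, FakeCohort())


class TestSdMapExport:
    def _field_and_structure(self, grid):
        center = (31.5,) * 3
        cohort = _cohort_of(
            grid,
            voxel_sphere(grid, center, 9.0, label="a"),
            voxel_sphere(grid, center, 11.0, label="b"),
        )
        structure = extract_median_structure(compute_coverage(cohort))
        return compute_distance_field(structure, cohort), structure

    def test_ply_roundtrip_and_sidecar(self, tmp_path, grid64):
        field, structure = self._field_and_structure(grid64)
        p = tmp_path / "sd.ply"
        sd_map_export(field, structure, p)
        verts, sd_cm, meta = read_sd_map(p)
        assert len(verts) == structure.surface.n_vertices
        assert np.allclose(sd_cm, field.local_sd_cm, atol=1e-4)
        assert meta["color_scale_cm"] == [0.1, 1.5]
        assert meta["sign_convention"] == "positive-outside"
        assert meta["clip_mm"] == 20.0
        assert meta["sd_ddof"] == 1

    def test_vtk_export(self, tmp_path, grid64):
        field, structure = self._field_and_structure(grid64)
        p = tmp_path / "sd.vtk"
        sd_map_export(field, structure, p)
        text = p.read_text()
        assert "POLYDATA" in text
        assert "local_sd_cm" in text
        assert json.loads((tmp_path / "sd.vtk.json").read_text())["clip_mm"] == 20.0

    def test_zero_noise_sd_channel_all_zero(self, tmp_path, grid64):
        s = voxel_sphere(grid64, (31.5,) * 3, 10.0)
        cohort = _cohort_of(
            grid64,
            s,
            BinaryMask(grid=grid64, voxels=s.voxels.copy(), label="b"),
        )
        structure = extract_median_structure(compute_coverage(cohort))
        field = compute_distance_field(structure, cohort)
        p = tmp_path / "zero.ply"
        sd_map_export(field, structure, p)
        _, sd_cm, _ = read_sd_map(p)
        assert np.all(sd_cm == 0.0)

    def test_subsampled_field_rejected(self, tmp_path, grid64):
        field, structure = self._field_and_structure(grid64)
        sub = compute_distance_field(
            structure,
            _cohort_of(
                grid64,
                voxel_sphere(grid64, (31.5,) * 3, 9.0, label="a"),
                voxel_sphere(grid64, (31.5,) * 3, 11.0, label="b"),
            ),
            max_points=50,
        )
        with pytest.raises(ValueError, match="subsample"):
            sd_map_export(sub, structure, tmp_path / "x.ply")
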