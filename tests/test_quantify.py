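"""Feature extraction: volumes, surfaces, skeletons, EDM thickness, cell counts."""

import numpy as np
import pytest
from scipy import ndimage

import gliaquant as gq
from gliaquant.quantify import (
    analyze_skeleton,
    count_cells,
    edm3d,
    extract_surface,
    full_report,
    reports_to_frame,
    skeletonize3d,
    thickness,
    volume_metrics,
)
from gliaquant.segmentation import BinaryMask3D

S26 = np.ones((3, 3, 3), dtype=bool)


def brute_force_surface(mask):
    """Foreground voxels with a 6-neighbour background (border counts as bg)."""
    fg = mask.astype(bool)
    count = 0
    nz, ny, nx = fg.shape
    for z, y, x in np.argwhere(fg):
        for dz, dy, dx in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            zz, yy, xx = z + dz, y + dy, x + dx
            if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx) or not fg[zz, yy, xx]:
                count += 1
                break
    return count


def brute_force_edm(mask, sampling):
    """O(n^2) nearest-background search in physical units."""
    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    out = np.zeros(mask.shape)
    if len(bg) == 0 or len(fg) == 0:
        return out
    sc = np.asarray(sampling, dtype=float)
    d = np.sqrt((((fg[:, None, :] - bg[None, :, :]) * sc) ** 2).sum(-1)).min(axis=1)
    out[tuple(fg.T)] = d
    return out


class TestVolumeAndSurface:
    def test_volume_and_coverage_arithmetic(self, rng):
        data = np.zeros((10, 10, 10), dtype=bool)
        data.ravel()[rng.choice(1000, 250, replace=False)] = True
        v, vc = volume_metrics(BinaryMask3D(data, (1, 1, 1)))
        assert v == pytest.approx(250.0)
        assert vc == pytest.approx(25.0)

    def test_empty_and_full_masks(self):
        empty = BinaryMask3D(np.zeros((4, 4, 4), dtype=bool), (1, 1, 1))
        full = BinaryMask3D(np.ones((4, 4, 4), dtype=bool), (0.5, 0.5, 0.5))
        assert volume_metrics(empty) == (0.0, 0.0)
        v, vc = volume_metrics(full)
        assert vc == 100.0
        assert v == pytest.approx(64 * 0.125)

    def test_anisotropic_voxel_volume(self):
        data = np.ones((2, 2, 2), dtype=bool)
        v, _ = volume_metrics(BinaryMask3D(data, (0.1, 0.2, 0.5)))
        assert v == pytest.approx(8 * 0.1 * 0.2 * 0.5)

    @pytest.mark.parametrize("size,expected", [(3, 26), (5, 98)])
    def test_cube_surface_counts(self, size, expected):
        cube, _ = gq.geometric_fixture("box", {"size": (size,) * 3})
        surf, s_n = extract_surface(cube)
        assert surf.count() == expected
        assert s_n == expected * 1.0

    def test_single_voxel_is_its_own_surface(self):
        data = np.zeros((3, 3, 3), dtype=bool)
        data[1, 1, 1] = True
        _, s_n = extract_surface(BinaryMask3D(data, (1, 1, 1)))
        assert s_n == 1.0

    def test_surface_matches_bruteforce_on_random_masks(self, rng):
        for _ in range(10):
            data = rng.random((7, 7, 7)) > 0.55
            surf, _ = extract_surface(BinaryMask3D(data, (1, 1, 1)))
            assert surf.count() == brute_force_surface(data)

    def test_border_touching_voxels_are_surface(self):
        # a full 3x3x3 image: only the center voxel has all 6 neighbours
        # in-bounds and foreground, so 26 of 27 voxels are surface
        data = np.ones((3, 3, 3), dtype=bool)
        surf, _ = extract_surface(BinaryMask3D(data, (1, 1, 1)))
        assert surf.count() == 26


class TestSkeleton:
    def test_thin_line_unchanged_and_classified(self):
        data = np.zeros((3, 50, 3), dtype=bool)
        data[1, :, 1] = True
        skel = skeletonize3d(BinaryMask3D(data, (1, 1, 1)))
        np.testing.assert_array_equal(skel.data, data)
        graph, (l_n, j_n, ep_n, bl_n) = analyze_skeleton(skel)
        assert (ep_n, j_n, len(graph.branches)) == (2, 0, 1)
        assert l_n == 50.0

    def test_solid_cylinder_reduces_to_single_path(self):
        cyl, _ = gq.geometric_fixture("cylinder", {"radius": 4, "length": 50})
        skel = skeletonize3d(cyl)
        _, npre = ndimage.label(cyl.data, structure=S26)
        _, npost = ndimage.label(skel.data, structure=S26)
        assert npre == npost == 1
        graph, (_, j_n, ep_n, _) = analyze_skeleton(skel)
        assert ep_n == 2
        assert j_n == 0

    def test_y_tube_has_three_endpoints_one_junction(self):
        yt, gt = gq.geometric_fixture("y_tube", {"arm_length": 10})
        graph, (_, j_n, ep_n, _) = analyze_skeleton(yt, (1, 1, 1))
        assert ep_n == gt.analytic["endpoints"] == 3
        assert j_n == gt.analytic["junctions"] == 1
        assert len(graph.branches) == 3

    def test_thick_y_tube_skeleton_keeps_topology(self):
        yt, _ = gq.geometric_fixture("y_tube", {"arm_length": 12, "radius": 2})
        skel = skeletonize3d(yt)
        graph, (_, j_n, ep_n, _) = analyze_skeleton(skel, (1, 1, 1))
        assert ep_n == 3
        assert j_n >= 1

    def test_torus_skeleton_is_a_cycle(self):
        torus, gt = gq.geometric_fixture("torus")
        skel = skeletonize3d(torus)
        graph, (_, _, ep_n, _) = analyze_skeleton(skel, (1, 1, 1))
        assert ep_n == gt.analytic["endpoints"] == 0
        assert graph.n_cycles >= gt.analytic["cycles"]
        _, npre = ndimage.label(torus.data, structure=S26)
        _, npost = ndimage.label(skel.data, structure=S26)
        assert npre == npost

    def test_empty_skeleton_all_zero(self):
        graph, (l_n, j_n, ep_n, bl_n) = analyze_skeleton(
            BinaryMask3D(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))
        )
        assert (l_n, j_n, ep_n, bl_n) == (0.0, 0, 0, 0.0)

    def test_isolated_voxel_is_one_endpoint_no_branch(self):
        data = np.zeros((3, 3, 3), dtype=bool)
        data[1, 1, 1] = True
        graph, (_, j_n, ep_n, _) = analyze_skeleton(BinaryMask3D(data, (1, 1, 1)))
        assert (ep_n, j_n, len(graph.branches)) == (1, 0, 0)

    def test_branch_lengths_use_euclidean_steps(self):
        # diagonal 10-step path in-plane: length 10*sqrt(2) in µm
        data = np.zeros((3, 12, 12), dtype=bool)
        for k in range(11):
            data[1, k, k] = True
        graph, _ = analyze_skeleton(BinaryMask3D(data, (1, 1, 1)))
        assert graph.branches[0].length_um == pytest.approx(10 * np.sqrt(2))


class TestEDMAndThickness:
    def test_single_voxel_distance_one(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        edm = edm3d(BinaryMask3D(data, (1, 1, 1)))
        assert edm.distances[2, 2, 2] == pytest.approx(1.0)

    def test_slab_center_plane_distance(self):
        slab, _ = gq.geometric_fixture("slab", {"thickness": 5})
        edm = edm3d(slab)
        # slab occupies 5 y-planes; center plane is 3 voxels from background
        center_y = 4 + 2
        assert edm.distances[10, center_y, 10] == pytest.approx(3.0)

    def test_matches_bruteforce_on_random_masks(self, rng):
        for _ in range(15):
            data = rng.random((9, 9, 9)) > 0.6
            vs = (1.0, 0.5, 2.0)
            edm = edm3d(BinaryMask3D(data, vs))
            np.testing.assert_allclose(
                edm.distances, brute_force_edm(data, (vs[2], vs[1], vs[0])), atol=1e-9
            )

    def test_edm_is_lipschitz(self, rng):
        data = rng.random((10, 10, 10)) > 0.5
        d = edm3d(BinaryMask3D(data, (1, 1, 1))).distances
        for axis in range(3):
            assert np.abs(np.diff(d, axis=axis)).max() <= 1.0 + 1e-9

    @pytest.mark.parametrize("r", [2, 3, 4, 5, 6])
    def test_cylinder_thickness_within_one_voxel(self, r):
        cyl, _ = gq.geometric_fixture("cylinder", {"radius": r, "length": 50})
        skel = skeletonize3d(cyl)
        t_n = thickness(skel, edm3d(cyl))
        assert abs(t_n - r) <= 1.0

    def test_line_mask_thickness_one(self):
        data = np.zeros((3, 20, 3), dtype=bool)
        data[1, 2:18, 1] = True
        mask = BinaryMask3D(data, (1, 1, 1))
        t_n = thickness(skeletonize3d(mask), edm3d(mask))
        assert t_n == pytest.approx(1.0)

    def test_adding_thin_branches_decreases_thickness(self):
        # developmental direction: protrusion growth lowers average thickness
        trunk = np.zeros((13, 60, 24), dtype=bool)
        zz, yy, xx = np.meshgrid(np.arange(13), np.arange(60), np.arange(24), indexing="ij")
        trunk |= ((zz - 6) ** 2 + (xx - 6) ** 2 <= 16) & (yy >= 5) & (yy < 55)
        with_branches = trunk.copy()
        for by in (15, 25, 35, 45):
            with_branches[6, by, 6:21] = True
        t_plain = thickness(
            skeletonize3d(BinaryMask3D(trunk, (1, 1, 1))), edm3d(BinaryMask3D(trunk, (1, 1, 1)))
        )
        mask_b = BinaryMask3D(with_branches, (1, 1, 1))
        t_branched = thickness(skeletonize3d(mask_b), edm3d(mask_b))
        assert t_branched < t_plain

    def test_dilation_monotonicity(self):
        cyl, _ = gq.geometric_fixture("cylinder", {"radius": 3, "length": 30})
        dilated = BinaryMask3D(
            ndimage.binary_dilation(cyl.data), cyl.voxel_size
        )
        v0, _ = volume_metrics(cyl)
        v1, _ = volume_metrics(dilated)
        assert v1 >= v0
        t0 = thickness(skeletonize3d(cyl), edm3d(cyl))
        t1 = thickness(skeletonize3d(dilated), edm3d(dilated))
        assert t1 >= t0 - 1e-9


class TestCountCells:
    @staticmethod
    def _spheres(centers, radius, shape=(20, 60, 80)):
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
        data = np.zeros(shape, dtype=bool)
        for cz, cy, cx in centers:
            data |= (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        return BinaryMask3D(data, (1, 1, 1))

    def test_five_disjoint_spheres(self):
        centers = [(10, 30, 8 + 16 * i) for i in range(5)]
        mask = self._spheres(centers, 5)
        assert count_cells(mask, roi_strategy="rectangle", roi_spec=(10, 50, 0, 80)) == 5

    def test_touching_spheres_split_by_watershed(self):
        mask = self._spheres([(10, 30, 30), (10, 30, 41)], 5.5)
        _, n = ndimage.label(mask.data, structure=S26)
        assert n == 1  # genuinely touching
        assert count_cells(mask, roi_strategy="rectangle", roi_spec=(15, 45, 15, 60)) == 2

    def test_empty_mask_counts_zero(self):
        empty = BinaryMask3D(np.zeros((5, 20, 20), dtype=bool), (1, 1, 1))
        assert count_cells(empty) == 0

    def test_degenerate_rectangle_rejected(self):
        mask = self._spheres([(10, 30, 30)], 4)
        with pytest.raises(ValueError, match="empty ROI"):
            count_cells(mask, roi_strategy="rectangle", roi_spec=(10, 10, 0, 80))

    def test_auto_band_finds_soma_layer(self, mg_phantom):
        _, truth, gt = mg_phantom
        assert count_cells(truth, roi_strategy="auto_band") == gt.n_cells


class TestFullReport:
    def test_box_report_internally_consistent(self):
        box, _ = gq.geometric_fixture("box", {"size": (6, 6, 6)}, voxel_size=(0.5, 0.5, 0.5))
        rep = full_report(None, box, filename="box", count_cells_roi=None)
        assert rep.SV_N == pytest.approx(rep.S_N / rep.V_N)
        assert 0 <= rep.VC_N <= 100

    def test_cylinder_report_matches_ground_truth(self):
        cyl, gt = gq.geometric_fixture("cylinder", {"radius": 5, "length": 50})
        rep = full_report(None, cyl, filename="cyl", count_cells_roi=None)
        assert rep.V_N == pytest.approx(gt.analytic["volume_continuum"], rel=0.06)
        assert rep.EP_N == 2
        assert rep.J_N == 0
        assert abs(rep.T_N - 5) <= 1.0

    def test_batch_frame_has_stable_columns(self):
        reports = [
            full_report(None, gq.geometric_fixture("box", {"size": (4, 4, 4)})[0],
                        filename=f"s{i}", count_cells_roi=None)
            for i in range(3)
        ]
        frame = reports_to_frame(reports)
        assert list(frame.columns) == [
            "file", "height_um", "V_N", "VC_N", "S_N", "SV_N",
            "L_N", "J_N", "EP_N", "BL_N", "T_N", "N_N",
        ]
        assert len(frame) == 3
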