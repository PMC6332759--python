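import numpy as np
import pytest
from scipy import ndimage

from ryrquant.dyads import (
    align_modalities,
    build_jsr,
    classify_dyadic,
    dilate_skeleton,
    export_mesh,
    pack_interface_ryrs,
    segment_tubules,
    skeletonize_tubules,
)
from ryrquant.simulate import generate_dyad_scene, generate_tubule_stack

from conftest import make_clusters


@pytest.fixture(scope="module")
def straight_geometry():
    skel = np.zeros((40, 60, 40), bool)
    skel[20, :, 20] = True
    return dilate_skeleton(skel, voxel_nm=10.0)


class TestSegmentTubules:
    def test_mean_threshold_covers_tubules(self, rng):
        stack = np.full((30, 30, 10), 10.0)
        tub = np.zeros_like(stack, bool)
        tub[5:8, :, 4:6] = True
        stack[tub] = 100.0
        stack += rng.normal(0, 0.5, stack.shape)
        mask = segment_tubules(stack, voxel_nm=100.0)
        assert mask[tub].all()

    def test_prune_boundary(self):
        # at 100 nm voxels one voxel is 1e-3 um^3: 10 voxels = 0.01 um^3
        # (pruned), 30 voxels = 0.03 um^3 (retained: rule removes < 0.03)
        stack = np.zeros((40, 40, 10))
        stack[2:12, 2, 2] = 100.0  # 10 voxels
        stack[20:30, 20:23, 5] = 100.0  # 30 voxels
        mask = segment_tubules(stack, voxel_nm=100.0)
        assert not mask[2:12, 2, 2].any()
        assert mask[20:30, 20:23, 5].all()

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError):
            segment_tubules(np.ones((5, 5, 5)), 100.0)


class TestSkeletonize:
    def test_straight_cylinder_recovers_axis(self):
        skel0 = np.zeros((30, 50, 30), bool)
        skel0[15, 5:45, 15] = True
        geom = dilate_skeleton(skel0, 10.0, diameter_nm=150.0)
        skel = skeletonize_tubules(geom.tubule_volume)
        pts = np.argwhere(skel)
        # away from the rounded end caps the centerline stays on the axis
        core = pts[(pts[:, 1] > 12) & (pts[:, 1] < 38)]
        assert len(core) > 0
        assert np.abs(core[:, [0, 2]] - 15).max() <= 1

    def test_sphere_collapses(self):
        seed = np.zeros((31, 31, 31), bool)
        seed[15, 15, 15] = True
        ball = ndimage.distance_transform_edt(~seed) <= 10
        skel = skeletonize_tubules(ball)
        assert skel.sum() <= 10

    def test_y_branch_has_single_degree3_node(self):
        skel0 = np.zeros((40, 40, 5), bool)
        skel0[20, 5:25, 2] = True
        for k in range(12):  # two diagonal arms
            skel0[20 - k, 24 + k, 2] = True
            skel0[20 + k, 24 + k, 2] = True
        mask = ndimage.binary_dilation(skel0, iterations=2)
        skel = skeletonize_tubules(mask)
        pts = {tuple(p) for p in np.argwhere(skel)}
        degree3 = 0
        for p in pts:
            nb = sum(
                1
                for q in pts
                if q != p and max(abs(a - b) for a, b in zip(p, q)) == 1
            )
            degree3 += nb >= 3
        assert degree3 >= 1
        # branch points are confined to one small neighbourhood
        branch_pts = [
            p
            for p in pts
            if sum(1 for q in pts if q != p and max(abs(a - b) for a, b in zip(p, q)) == 1) >= 3
        ]
        branch_pts = np.array(branch_pts)
        assert np.ptp(branch_pts, axis=0).max() <= 3


class TestDilateSkeleton:
    def test_cross_section_diameter(self, straight_geometry):
        cross = straight_geometry.tubule_volume[:, 30, :]
        width_nm = cross.sum(axis=0).max() * 10.0
        assert abs(width_nm - 250.0) <= 10.0

    def test_cleft_shell_one_voxel(self, straight_geometry):
        geom = straight_geometry
        assert geom.jsr_mask.any()
        assert not (geom.jsr_mask & geom.tubule_volume).any()
        # every shell voxel touches the tubule surface (one-voxel shell)
        grown = ndimage.binary_dilation(geom.tubule_volume, np.ones((3, 3, 3), bool))
        assert (geom.jsr_mask & ~grown).sum() == 0

    def test_distance_transform_oracle(self, straight_geometry):
        geom = straight_geometry
        dist = ndimage.distance_transform_edt(~geom.skeleton, sampling=10.0)
        assert np.array_equal(geom.tubule_volume, dist <= 125.0)
        assert np.array_equal(geom.jsr_mask, (dist <= 135.0) & (dist > 125.0))

    def test_too_small_diameter_rejected(self):
        skel = np.zeros((5, 5, 5), bool)
        skel[2, 2, 2] = True
        with pytest.raises(ValueError):
            dilate_skeleton(skel, voxel_nm=10.0, diameter_nm=15.0)


class TestAlignment:
    def test_identity_landmarks(self):
        pts = np.random.default_rng(0).uniform(0, 5000, size=(6, 3))
        pairs = np.stack([pts, pts], axis=1)
        tf = align_modalities(pairs)
        assert tf.scale == pytest.approx(1.0)
        assert np.allclose(tf.translation_nm, 0.0, atol=1e-6)

    def test_apply_and_recover(self):
        r = np.random.default_rng(1)
        src = r.uniform(0, 20_000, size=(8, 3))
        true_scale, true_t = 1.02, np.array([500.0, -300.0, 200.0])
        dst = true_scale * src + true_t
        tf = align_modalities(np.stack([src, dst], axis=1))
        assert tf.scale == pytest.approx(true_scale, rel=0.005)
        assert np.allclose(tf.translation_nm, true_t, atol=10.0)

    def test_residual_tracks_landmark_noise(self):
        r = np.random.default_rng(2)
        src = r.uniform(0, 20_000, size=(40, 3))
        sigma = 20.0
        dst = src + r.normal(0, sigma, src.shape)
        tf = align_modalities(np.stack([src, dst], axis=1))
        assert tf.residual_rms_nm <= sigma * np.sqrt(2)

    def test_axial_shift_refined_from_z_profiles(self):
        r = np.random.default_rng(3)
        base = r.random((20, 20, 40))
        base[:, :, :8] = 0.0
        base[:, :, 30:] = 0.0
        shifted = np.roll(base, 5, axis=2)  # 50 nm at 10 nm voxels
        src = r.uniform(0, 2000, size=(5, 3))
        pairs = np.stack([src, src], axis=1)
        tf = align_modalities(pairs, dstorm_ryr=base, confocal_ryr=shifted, voxel_nm=10.0)
        assert tf.translation_nm[2] == pytest.approx(50.0, abs=10.0)

    def test_degenerate_landmarks_rejected(self):
        pairs = np.stack([np.ones((3, 3)), np.ones((3, 3))], axis=1)
        with pytest.raises(ValueError):
            align_modalities(pairs)


class TestClassifyDyadic:
    def test_overlap_with_jsr_is_dyadic(self, straight_geometry):
        # a cluster voxel landing inside the cleft shell
        shell_pt = np.argwhere(straight_geometry.jsr_mask)[0]
        nm = (shell_pt + 0.5) * 10.0
        cs = make_clusters([[tuple((nm // 30).astype(int))]])
        model = classify_dyadic(cs, straight_geometry)
        assert model.dyadic_cluster_ids == [0]

    def test_far_centroid_is_nondyadic(self):
        skel = np.zeros((80, 20, 40), bool)
        skel[5, :, 20] = True
        geom = dilate_skeleton(skel, 10.0)
        # centroid ~300 nm from the skeleton, no jSR overlap
        cs = make_clusters([[(12, 3, 6)]])  # (375, 105, 195) nm vs skeleton x=55
        model = classify_dyadic(cs, geom)
        assert model.nondyadic_cluster_ids == [0]

    def test_planted_fractions_recovered(self):
        cs, geom, truth = generate_dyad_scene(n_clusters=150, seed=4)
        model = classify_dyadic(cs, geom)
        frac = model.nondyadic_fraction
        assert abs(frac - 0.15) <= 0.03

    def test_fraction_monotone_in_threshold(self):
        cs, geom, _ = generate_dyad_scene(n_clusters=80, seed=9)
        fracs = []
        for thr in (50.0, 150.0, 250.0, 400.0, 600.0):
            m = classify_dyadic(cs, geom, threshold_nm=thr)
            fracs.append(len(m.dyadic_cluster_ids))
        assert fracs == sorted(fracs)

    def test_empty_geometry_warns_all_nondyadic(self, straight_geometry):
        import dataclasses

        empty = dataclasses.replace(
            straight_geometry, skeleton=np.zeros_like(straight_geometry.skeleton)
        )
        cs = make_clusters([[(1, 1, 1)]])
        with pytest.warns(UserWarning):
            model = classify_dyadic(cs, empty)
        assert model.nondyadic_cluster_ids == [0]


class TestPacking:
    def _planar_patch_geometry(self):
        """A flat jSR 'shelf': a 90 x 90 nm planar patch of shell voxels."""
        import dataclasses

        shape = (20, 20, 8)
        jsr = np.zeros(shape, bool)
        jsr[5:14, 5:14, 3] = True
        skel = np.zeros(shape, bool)
        skel[9, 9, 0] = True
        return dataclasses.replace(
            dilate_skeleton(skel, 10.0, diameter_nm=20.0, cleft_nm=10.0), jsr_mask=jsr
        )

    def test_90nm_patch_packs_nine(self):
        geom = self._planar_patch_geometry()
        cs = make_clusters([[(2, 2, 1), (3, 2, 1), (2, 3, 1), (3, 3, 1)]])
        pos = pack_interface_ryrs(cs.clusters[0], cs, geom, reach_nm=1e9)
        assert len(pos) == 9

    def test_packed_spacing_at_least_30nm(self):
        geom = self._planar_patch_geometry()
        cs = make_clusters([[(2, 2, 1), (3, 3, 1)]])
        pos = pack_interface_ryrs(cs.clusters[0], cs, geom, reach_nm=1e9)
        d = np.sqrt(((pos[:, None] - pos[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 30.0 - 1e-6

    def test_count_cap(self):
        geom = self._planar_patch_geometry()
        cs = make_clusters([[(2, 2, 1)]])
        pos = pack_interface_ryrs(cs.clusters[0], cs, geom, max_count=4, reach_nm=1e9)
        assert len(pos) == 4


class TestBuildJsr:
    def test_terminal_confined_to_shell_and_padding(self, straight_geometry):
        geom = straight_geometry
        seed_pt = np.argwhere(geom.jsr_mask)[100]
        nm = (seed_pt + 0.5) * 10.0
        term = build_jsr(nm[None, :], geom, padding_nm=80.0)
        assert term.any()
        assert not (term & ~geom.jsr_mask).any()
        pts = (np.argwhere(term) + 0.5) * 10.0
        assert np.abs(pts - nm).max() <= 80.0 + 5.0

    def test_l1_ball_oracle_on_open_shell(self):
        import dataclasses

        shape = (30, 30, 6)
        jsr = np.zeros(shape, bool)
        jsr[:, :, 2] = True  # unobstructed plane: geodesic == L1 ball
        skel = np.zeros(shape, bool)
        skel[0, 0, 0] = True
        geom = dataclasses.replace(
            dilate_skeleton(skel, 10.0, diameter_nm=20.0), jsr_mask=jsr
        )
        center = np.array([[145.0, 145.0, 25.0]])
        term = build_jsr(center, geom, padding_nm=80.0)
        idx = np.argwhere(term)
        l1 = np.abs((idx + 0.5) * 10.0 - center).sum(axis=1)
        seed_idx = np.floor(center / 10.0).astype(int)[0]
        expected = np.zeros(shape, bool)
        for p in np.argwhere(jsr):
            if np.abs(p - seed_idx).sum() <= 8:
                expected[tuple(p)] = True
        assert np.array_equal(term, expected)

    def test_empty_positions_empty_terminal(self, straight_geometry):
        term = build_jsr(np.empty((0, 3)), straight_geometry, 80.0)
        assert not term.any()


class TestMeshExport:
    def test_sphere_area_within_5pct(self, tmp_path):
        import dataclasses

        seed = np.zeros((61, 61, 61), bool)
        seed[30, 30, 30] = True
        ball = ndimage.distance_transform_edt(~seed, sampling=10.0) <= 200.0
        geom = dataclasses.replace(
            dilate_skeleton(seed, 10.0, diameter_nm=40.0), tubule_volume=ball
        )
        files = export_mesh(geom, None, tmp_path)
        import trimesh

        mesh = trimesh.load(files[0])
        assert mesh.is_watertight
        analytic = 4 * np.pi * 200.0**2
        assert mesh.area == pytest.approx(analytic, rel=0.05)

    def test_empty_model_writes_nothing(self, tmp_path):
        import dataclasses

        skel = np.zeros((10, 10, 10), bool)
        skel[5, 5, 5] = True
        geom = dilate_skeleton(skel, 10.0, diameter_nm=30.0)
        empty = dataclasses.replace(geom, tubule_volume=np.zeros_like(geom.tubule_volume))
        files = export_mesh(empty, None, tmp_path / "sub")
        assert files == []


class TestSyntheticRecovery:
    def test_end_to_end_classification_accuracy(self):
        cs, geom, truth = generate_dyad_scene(n_clusters=200, seed=3)
        model = classify_dyadic(cs, geom)
        pred = np.zeros(len(cs), bool)
        pred[list(model.dyadic_cluster_ids)] = True
        assert (pred == truth.dyadic_labels).mean() >= 0.97

    def test_tubule_stack_skeleton_recovery(self):
        stack, truth = generate_tubule_stack(
            shape_um=(4.0, 4.0, 2.0), psf_sigma_nm=(0.0, 0.0, 0.0),
            photons_per_voxel=200.0, background=0.5, seed=2,
        )
        mask = segment_tubules(stack, voxel_nm=100.0)
        tub = truth.extras["tubule_mask"]
        assert mask[tub].mean() > 0.99
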