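import numpy as np
import pytest

from ryrquant.volumes import (
    AnalysisVolume,
    ThresholdError,
    binarize_otsu,
    downscale,
    project_2d,
    project_clusters,
    project_mask,
    render_gaussian,
    segment_clusters,
)

from conftest import make_table


def brute_force_otsu(values, nbins=256):
    """Exhaustive search over histogram thresholds maximizing between-class
    variance; independent oracle for the Otsu step."""
    hist, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_v = edges[1], -1.0
    total = hist.sum()
    for k in range(1, nbins):
        w0, w1 = hist[:k].sum(), hist[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:k] * centers[:k]).sum() / w0
        m1 = (hist[k:] * centers[k:]).sum() / w1
        v = (w0 / total) * (w1 / total) * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, edges[k]  # threshold at the split edge
    return best_t


class TestRenderGaussian:
    def test_single_event_unit_mass(self):
        vol = render_gaussian(make_table([[0, 0, 0]]), voxel_nm=10)
        assert vol.intensity.sum() == pytest.approx(1.0, abs=0.01)
        assert vol.n_events == 1

    def test_two_identical_events_are_linear(self):
        t1 = make_table([[0, 0, 0]])
        t2 = make_table([[0, 0, 0], [0, 0, 0]], frames=[0, 1])
        v1 = render_gaussian(t1, voxel_nm=10)
        v2 = render_gaussian(t2, voxel_nm=10)
        assert np.allclose(v2.intensity, 2 * v1.intensity)
        assert v2.n_events == 2

    def test_second_moments_recover_precision(self):
        vol = render_gaussian(make_table([[0, 0, 0]], precisions=(32, 64)), voxel_nm=10)
        idx = np.indices(vol.intensity.shape).reshape(3, -1).T
        centers = vol.voxel_centers(idx)
        w = vol.intensity.ravel()
        mean = (centers * w[:, None]).sum(axis=0) / w.sum()
        var = (w[:, None] * (centers - mean) ** 2).sum(axis=0) / w.sum()
        sigma = np.sqrt(var)
        # 3-sigma truncation narrows the second moment slightly; compare
        # against the truncated-Gaussian expectation within 5%
        trunc = np.sqrt(1 - 2 * 3 * np.exp(-4.5) / (np.sqrt(2 * np.pi) * 0.9973))
        assert sigma[0] == pytest.approx(32 * trunc, rel=0.05)
        assert sigma[1] == pytest.approx(32 * trunc, rel=0.05)
        assert sigma[2] == pytest.approx(64 * trunc, rel=0.05)

    def test_rejects_nonpositive_voxel(self):
        with pytest.raises(ValueError):
            render_gaussian(make_table([[0, 0, 0]]), voxel_nm=0)


class TestDownscale:
    def test_block_sum_of_ones(self):
        vol = AnalysisVolume(
            np.ones((3, 3, 3)), np.zeros((3, 3, 3), int), (10.0,) * 3, (0.0,) * 3
        )
        out = downscale(vol, 30.0)
        assert out.intensity.shape == (1, 1, 1)
        assert out.intensity[0, 0, 0] == pytest.approx(27.0)

    def test_event_count_conserved(self, rng):
        t = make_table(rng.uniform(0, 900, size=(500, 3)), frames=np.arange(500))
        vol = render_gaussian(t, voxel_nm=10)
        out = downscale(vol, 30.0)
        assert out.n_events == vol.n_events == 500

    def test_counts_match_direct_binning_oracle(self, rng):
        xyz = rng.uniform(50, 850, size=(1000, 3))
        t = make_table(xyz, frames=np.arange(1000))
        vol = render_gaussian(t, voxel_nm=10)
        out = downscale(vol, 30.0)
        origin = np.asarray(out.origin_nm)
        idx = np.floor((xyz - origin) / 30.0).astype(int)
        expected = np.zeros(out.event_count.shape, int)
        np.add.at(expected, tuple(idx.T), 1)
        assert np.array_equal(out.event_count, expected)

    def test_noninteger_ratio_rejected(self):
        vol = AnalysisVolume(
            np.ones((3, 3, 3)), np.zeros((3, 3, 3), int), (10.0,) * 3, (0.0,) * 3
        )
        with pytest.raises(ValueError):
            downscale(vol, 25.0)


class TestOtsu:
    def _vol(self, arr):
        arr = np.asarray(arr, dtype=float)
        return AnalysisVolume(arr, np.zeros(arr.shape, int), (30.0,) * arr.ndim, (0.0,) * arr.ndim)

    def test_threshold_separates_bimodal_modes(self, rng):
        arr = np.full((10, 10, 10), 0.1)
        arr[2:5, 2:5, 2:5] = 1.0
        arr += rng.normal(0, 0.005, arr.shape)
        vol = self._vol(np.clip(arr, 1e-6, None))
        mask = binarize_otsu(vol)
        assert mask.sum() == 27
        assert mask[2:5, 2:5, 2:5].all()

    def test_matches_brute_force_oracle(self, rng):
        arr = np.zeros((12, 12, 12))
        arr.ravel()[rng.choice(arr.size, 400, replace=False)] = rng.uniform(0.05, 0.3, 400)
        arr.ravel()[rng.choice(arr.size, 60, replace=False)] = rng.uniform(0.8, 1.2, 60)
        vol = self._vol(arr)
        mask = binarize_otsu(vol)
        thr = brute_force_otsu(arr[arr > 0])
        assert np.array_equal(mask, arr > thr)

    def test_blob_on_empty_background(self):
        arr = np.zeros((10, 10, 10))
        arr[4:7, 4:7, 4:7] = 1.0
        arr[0, 0, 0] = 0.01  # a whisper of background so the histogram has 2 classes
        mask = binarize_otsu(self._vol(arr))
        expected = arr >= 1.0
        assert np.array_equal(mask, expected)

    def test_constant_volume_rejected(self):
        with pytest.raises(ThresholdError):
            binarize_otsu(self._vol(np.full((5, 5, 5), 3.0)))


class TestSegmentation:
    def _vol_like(self, mask, counts=None):
        counts = counts if counts is not None else mask.astype(int)
        return AnalysisVolume(mask.astype(float), counts, (30.0,) * mask.ndim, (0.0,) * mask.ndim)

    def test_two_separated_blobs(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[1:3, 1:3, 1:3] = True
        mask[6:8, 6:8, 6:8] = True
        cs = segment_clusters(mask, self._vol_like(mask))
        assert len(cs) == 2

    def test_diagonal_contact_is_one_cluster(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        cs = segment_clusters(mask, self._vol_like(mask))
        assert len(cs) == 1

    def test_planted_blobs_event_bookkeeping(self, rng):
        mask = np.zeros((40, 40, 8), bool)
        counts = np.zeros(mask.shape, int)
        planted = []
        for k in range(50):
            i, j = 4 * (k % 10) + 1, 4 * (k // 10) + 1
            mask[i : i + 2, j : j + 2, 2:4] = True
            c = int(rng.integers(1, 20))
            counts[i, j, 2] = c
            planted.append(c)
        cs = segment_clusters(mask, self._vol_like(mask, counts))
        assert len(cs) == 50
        assert sorted(c.event_count for c in cs) == sorted(planted)

    def test_segmentation_invariant_to_event_order(self, rng):
        xyz = rng.uniform(0, 2000, size=(300, 3))
        perm = rng.permutation(300)
        v1 = downscale(render_gaussian(make_table(xyz, frames=np.zeros(300, int)), 10), 30)
        v2 = downscale(
            render_gaussian(make_table(xyz[perm], frames=np.zeros(300, int)), 10), 30
        )
        m1, m2 = binarize_otsu(v1), binarize_otsu(v2)
        assert np.array_equal(m1, m2)
        c1 = segment_clusters(m1, v1)
        c2 = segment_clusters(m2, v2)
        assert sorted(c.event_count for c in c1) == sorted(c.event_count for c in c2)

    def test_empty_mask_gives_empty_set(self):
        mask = np.zeros((5, 5, 5), bool)
        assert len(segment_clusters(mask, self._vol_like(mask))) == 0


def test_tiff_stack_round_trip(tmp_path, rng):
    from ryrquant.imagestacks import read_stack, write_mask, write_stack

    vol = rng.random((7, 5, 3)).astype(np.float32)
    p = tmp_path / "v.tif"
    write_stack(vol, p)
    assert np.allclose(read_stack(p), vol)
    mask = vol > 0.5
    write_mask(mask, tmp_path / "m.tif")
    assert np.array_equal(read_stack(tmp_path / "m.tif") > 0, mask)


class TestProjection:
    def test_stacked_clusters_merge_in_2d(self):
        mask = np.zeros((6, 6, 12), bool)
        mask[2:4, 2:4, 1:3] = True
        mask[2:4, 2:4, 8:10] = True
        vol = AnalysisVolume(mask.astype(float), mask.astype(int), (30.0,) * 3, (0.0,) * 3)
        cs3 = segment_clusters(mask, vol)
        cs2 = project_clusters(cs3, vol)
        assert len(cs3) == 2
        assert len(cs2) == 1

    def test_flat_cluster_footprint_preserved(self):
        mask = np.zeros((8, 8, 4), bool)
        mask[2:5, 3:6, 1] = True
        assert np.array_equal(project_mask(mask), mask.any(axis=2))

    def test_projection_conserves_event_count(self, rng):
        t = make_table(rng.uniform(0, 1500, size=(400, 3)), frames=np.arange(400))
        vol = downscale(render_gaussian(t, 10), 30)
        assert project_2d(vol).n_events == vol.n_events

    def test_projection_never_splits_clusters(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            mask = r.random((15, 15, 6)) > 0.93
            vol = AnalysisVolume(
                mask.astype(float), mask.astype(int), (30.0,) * 3, (0.0,) * 3
            )
            cs3 = segment_clusters(mask, vol)
            cs2 = project_clusters(cs3, vol)
            assert len(cs2) <= len(cs3)
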