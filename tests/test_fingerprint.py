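import numpy as np
import pytest

from mousetrack import (
    Correlogram,
    FingerprintParams,
    buffer_and_crop,
    compute_correlogram,
    dissimilarity,
    fingerprint_region,
)
from mousetrack.fingerprint import buffered_mask
from mousetrack.segmentation import RegionFromMask

from oracles import buffered_mask_naive, correlogram_naive

IDENTITY = FingerprintParams(dilation_iters=0, blur_kernel=1, downscale=1)


def _region(frame_shape, mask):
    return RegionFromMask.build(0, mask)


class TestBufferAndCrop:
    def test_identity_configuration_returns_raw_masked_crop(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:15, 12:20] = True
        patch, pmask = buffer_and_crop(frame, _region((32, 32), mask), IDENTITY)
        expected = frame[10:15, 12:20].astype(float)
        np.testing.assert_array_equal(patch, expected)
        assert pmask.all()

    def test_dilation_grows_single_pixel_support(self):
        frame = np.full((64, 64), 128, dtype=np.uint8)
        mask = np.zeros((64, 64), dtype=bool)
        mask[32, 32] = True
        patch, pmask = buffer_and_crop(frame, _region((64, 64), mask), FingerprintParams())
        assert pmask.sum() > 1

    def test_buffered_support_matches_naive_morphology(self):
        rng = np.random.default_rng(5)
        mask = np.zeros((40, 40), dtype=bool)
        ys, xs = np.mgrid[0:40, 0:40]
        mask[((ys - 20) / 8.0) ** 2 + ((xs - 20) / 5.0) ** 2 <= 1] = True
        params = FingerprintParams(dilation_iters=3, dilation_kernel=3, blur_kernel=7, downscale=1)
        ours = buffered_mask(mask, params)
        ref = buffered_mask_naive(mask, iters=3, ksize=3, blur=7)
        np.testing.assert_array_equal(ours, ref)

    def test_empty_mask_is_an_error(self):
        frame = np.zeros((8, 8), dtype=np.uint8)
        region = RegionFromMask.build(0, np.ones((8, 8), dtype=bool))
        region.mask[:] = False
        with pytest.raises(ValueError, match="empty"):
            buffer_and_crop(frame, region, IDENTITY)


class TestComputeCorrelogram:
    def test_single_pixel_gives_zero_correlogram(self):
        patch = np.array([[7.0]])
        mask = np.array([[True]])
        c = compute_correlogram(patch, mask, IDENTITY)
        assert c.total_pairs == 0
        assert c.hist.sum() == 0

    def test_two_pixel_patch_lands_in_hand_computed_bin(self):
        # d = 1 -> bin floor(1/64*32) = 0; s = 30 -> bin floor(30/511*32) = 1
        patch = np.array([[10.0, 20.0]])
        mask = np.array([[True, True]])
        c = compute_correlogram(patch, mask, IDENTITY)
        assert c.total_pairs == 1
        assert c.hist[0, 1] == 1.0
        assert c.hist.sum() == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        patch = rng.integers(0, 256, size=(8, 8)).astype(float)
        mask = rng.random((8, 8)) < 0.7
        if mask.sum() < 2:
            mask[0, 0] = mask[7, 7] = True
        params = IDENTITY
        ours = compute_correlogram(patch, mask, params)
        ref_hist, ref_total = correlogram_naive(
            patch, mask, params.n_dist_bins, params.n_sum_bins, params.max_dist_px
        )
        assert ours.total_pairs == ref_total
        np.testing.assert_array_equal(
            np.round(ours.hist * ours.total_pairs).astype(np.int64), ref_hist
        )

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        tile = rng.integers(0, 256, size=(6, 6)).astype(float)
        small = np.zeros((20, 20))
        small[2:8, 2:8] = tile
        big = np.zeros((20, 20))
        big[11:17, 12:18] = tile
        m1 = np.zeros((20, 20), dtype=bool)
        m1[2:8, 2:8] = True
        m2 = np.zeros((20, 20), dtype=bool)
        m2[11:17, 12:18] = True
        c1 = compute_correlogram(small, m1, IDENTITY)
        c2 = compute_correlogram(big, m2, IDENTITY)
        np.testing.assert_array_equal(c1.hist, c2.hist)

    def test_rotation_by_90_degrees_invariance(self):
        rng = np.random.default_rng(2)
        patch = rng.integers(0, 256, size=(7, 5)).astype(float)
        mask = rng.random((7, 5)) < 0.8
        mask[0, 0] = mask[-1, -1] = True
        c1 = compute_correlogram(patch, mask, IDENTITY)
        c2 = compute_correlogram(np.rot90(patch), np.rot90(mask), IDENTITY)
        np.testing.assert_array_equal(c1.hist, c2.hist)

    def test_max_pairs_subsampling_is_seeded_and_bounded(self):
        rng = np.random.default_rng(3)
        patch = rng.integers(0, 256, size=(10, 10)).astype(float)
        mask = np.ones((10, 10), dtype=bool)
        params = FingerprintParams(
            dilation_iters=0, blur_kernel=1, downscale=1, max_pairs=100, pair_seed=9
        )
        c1 = compute_correlogram(patch, mask, params)
        c2 = compute_correlogram(patch, mask, params)
        assert c1.total_pairs == 100
        np.testing.assert_array_equal(c1.hist, c2.hist)


class TestDissimilarity:
    def _random_normalized(self, rng, shape=(32, 32)):
        h = rng.random(shape)
        return Correlogram(hist=h / h.sum(), total_pairs=100)

    def test_identity_symmetry_and_range_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = self._random_normalized(rng)
            b = self._random_normalized(rng)
            assert dissimilarity(a, a) == 0.0
            assert dissimilarity(a, b) == dissimilarity(b, a)
            assert 0.0 <= dissimilarity(a, b) <= 2.0 / (32 * 32)

    def test_disjoint_one_hot_closed_form(self):
        h1 = np.zeros((32, 32))
        h1[0, 0] = 1.0
        h2 = np.zeros((32, 32))
        h2[5, 7] = 1.0
        a, b = Correlogram(h1, 10), Correlogram(h2, 10)
        assert dissimilarity(a, b) == pytest.approx(2.0 / 1024.0)

    def test_dimension_mismatch_is_an_error(self):
        a = Correlogram(np.zeros((32, 32)), 0)
        b = Correlogram(np.zeros((16, 32)), 0)
        with pytest.raises(ValueError, match="shapes differ"):
            dissimilarity(a, b)


def test_same_animal_more_similar_than_other_animal(small_scene):
    """Fingerprints discriminate textures: consecutive-frame self-dissimilarity
    is below same-frame cross-animal dissimilarity."""
    from mousetrack import SegmentationParams, segment_frame

    params = FingerprintParams()
    seg = SegmentationParams(min_area_px=100)
    truth = small_scene.truth().table

    def by_truth_id(regions, t):
        tt = truth[truth["frame"] == t].set_index("id")
        out = {}
        for r in regions:
            cx, cy = r.centroid
            d = np.hypot(tt["cx_px"] - cx, tt["cy_px"] - cy)
            out[int(d.idxmin())] = r
        return out

    worse = 0
    for t in range(20):
        fa, fb = small_scene.render_frame(t), small_scene.render_frame(t + 1)
        ra = by_truth_id(segment_frame(fa, seg, t), t)
        rb = by_truth_id(segment_frame(fb, seg, t + 1), t + 1)
        assert set(ra) == set(rb) == {0, 1}
        fps_a = {i: fingerprint_region(fa, r, params) for i, r in ra.items()}
        fps_b = {i: fingerprint_region(fb, r, params) for i, r in rb.items()}
        same = dissimilarity(fps_a[0], fps_b[0])
        cross = dissimilarity(fps_a[0], fps_a[1])
        if same >= cross:
            worse += 1
    assert worse == 0
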