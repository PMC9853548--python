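import numpy as np
import pytest

from mousetrack import (
    SegmentationParams,
    expand_contour,
    segment_frame,
    simplify_rdp,
)
from mousetrack.segmentation import RegionFromMask

from oracles import dilate_disk_naive, rdp_closed_naive
from conftest import random_polygon


class TestSegmentFrame:
    def test_uniform_white_frame_yields_nothing(self):
        frame = np.full((64, 64), 255, dtype=np.uint8)
        assert segment_frame(frame, SegmentationParams(threshold=128)) == []

    def test_two_ellipses_detected_with_exact_areas(self, small_scene):
        frame = small_scene.render_frame(0)
        truth_masks = small_scene.render_masks(0)
        regions = segment_frame(frame, SegmentationParams(min_area_px=100))
        assert len(regions) == 2
        # detected areas equal rendered ground-truth pixel counts exactly
        detected = sorted(r.area_px for r in regions)
        expected = sorted(int(m.sum()) for m in truth_masks.values())
        assert detected == expected
        # and each detected mask equals a ground-truth mask pixel-for-pixel
        for r in regions:
            assert any(
                np.array_equal(r.full_mask(), m) for m in truth_masks.values()
            )

    def test_min_area_filter_drops_small_blob(self, small_scene):
        frame = small_scene.render_frame(0)
        areas = sorted(
            r.area_px for r in segment_frame(frame, SegmentationParams(min_area_px=100))
        )
        params = SegmentationParams(min_area_px=areas[0] + 1)
        assert len(segment_frame(frame, params)) == 1

    def test_descending_area_order_and_determinism(self, small_scene):
        frame = small_scene.render_frame(5)
        params = SegmentationParams(min_area_px=100)
        r1 = segment_frame(frame, params)
        r2 = segment_frame(frame, params)
        assert [r.area_px for r in r1] == sorted(
            (r.area_px for r in r1), reverse=True
        )
        assert [r.centroid for r in r1] == [r.centroid for r in r2]

    def test_eight_connectivity_keeps_diagonal_limbs_together(self):
        frame = np.full((16, 16), 255, dtype=np.uint8)
        for k in range(6):  # diagonal line of single dark pixels
            frame[4 + k, 4 + k] = 0
        regions = segment_frame(frame, SegmentationParams(threshold=128, min_area_px=0, max_area_px=100))
        assert len(regions) == 1
        assert regions[0].area_px == 6


class TestExpandContour:
    def _square_region(self, size=10, at=(20, 20), frame=(64, 64)):
        mask = np.zeros(frame, dtype=bool)
        mask[at[0] : at[0] + size, at[1] : at[1] + size] = True
        return RegionFromMask.build(0, mask)

    def test_zero_expansion_is_identity(self):
        region = self._square_region()
        out = expand_contour(region, 0)
        np.testing.assert_array_equal(out.full_mask(), region.full_mask())

    def test_expansion_matches_bruteforce_disk_dilation(self):
        region = self._square_region()
        out = expand_contour(region, 5)
        expected = dilate_disk_naive(region.full_mask(), 5)
        np.testing.assert_array_equal(out.full_mask(), expected)
        h, w = out.mask.shape
        assert (h, w) == (20, 20)
        assert out.area_px > region.area_px

    def test_expansion_clipped_at_frame_edge(self):
        region = self._square_region(at=(0, 0), frame=(16, 16))
        out = expand_contour(region, 5)
        full = out.full_mask()
        assert full.shape == (16, 16)
        expected = dilate_disk_naive(region.full_mask(), 5)
        np.testing.assert_array_equal(full, expected)
        # contour vertices stay within frame bounds
        assert out.contour[:, 0].min() >= -1 and out.contour[:, 0].max() <= 16
        assert out.contour[:, 1].min() >= -1 and out.contour[:, 1].max() <= 16


def _chain_distance(p, a, b):
    """Distance from point p to segment ab."""
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-12), 0, 1)
    return np.hypot(*(a + t * ab - p))


def _max_dist_to_polyline(original, simplified):
    closed = np.vstack([simplified, simplified[:1]])
    out = 0.0
    for p in original:
        d = min(
            _chain_distance(p, closed[i], closed[i + 1]) for i in range(len(closed) - 1)
        )
        out = max(out, d)
    return out


class TestRdp:
    def test_collinear_middle_point_removed(self):
        poly = np.array([(0, 0), (1, 0), (2, 0), (2, 2), (0, 2)], dtype=float)
        out = simplify_rdp(poly, 0.5)
        assert len(out) == 4
        assert not any(np.array_equal(v, [1, 0]) for v in out)

    def test_zero_epsilon_is_identity(self):
        rng = np.random.default_rng(0)
        poly = random_polygon(rng, 25)
        np.testing.assert_array_equal(simplify_rdp(poly, 0.0), poly)

    def test_degenerate_collinear_polygon_reduces_to_extremes(self):
        poly = np.array([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0), (3.0, 0.0)])
        out = simplify_rdp(poly, 0.5)
        assert len(out) == 2
        np.testing.assert_allclose(sorted(out[:, 0]), [0.0, 3.0])

    @pytest.mark.parametrize("epsilon", [0.0, 0.5, 1.5, 5.0])
    def test_matches_naive_recursive_oracle(self, epsilon):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            poly = random_polygon(rng, 40)
            ours = simplify_rdp(poly, epsilon)
            ref = rdp_closed_naive(poly, epsilon)
            np.testing.assert_allclose(ours, ref)

    def test_epsilon_distance_bound_and_monotonicity(self):
        rng = np.random.default_rng(7)
        eps_grid = [0.0, 0.25, 0.5, 1.0, 1.5, 3.0, 5.0]
        for _ in range(10):
            poly = random_polygon(rng, 40)
            sizes = []
            for eps in eps_grid:
                out = simplify_rdp(poly, eps)
                sizes.append(len(out))
                assert _max_dist_to_polyline(poly, out) <= eps + 1e-9
            assert sizes == sorted(sizes, reverse=True)
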