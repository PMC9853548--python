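import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mousetrack import (
    CorrectionParams,
    SwapDirective,
    apply_swaps,
    detect_warnings,
    fill_misses,
    mark_warnings,
)
from mousetrack.io import make_track_table


def table_from_positions(positions: dict[int, list[tuple[float, float]]]):
    """positions[id] = [(x, y) per frame]; None marks a miss."""
    rows = []
    for i, traj in positions.items():
        for f, p in enumerate(traj):
            if p is None:
                continue
            rows.append(
                {"frame": f, "id": i, "cx_px": float(p[0]), "cy_px": float(p[1]),
                 "area_px": 100.0}
            )
    return make_track_table(rows)


class TestFillMisses:
    def test_gapless_table_unchanged(self):
        t = table_from_positions({0: [(0, 0), (1, 1)], 1: [(5, 5), (6, 6)]})
        out, gaps = fill_misses(t)
        pd.testing.assert_frame_equal(out, t)
        assert gaps == []

    def test_single_frame_miss_copied_from_previous_frame(self):
        t = table_from_positions(
            {0: [(0, 0), (1, 1), (2, 2)], 2: [(9, 9), None, (7, 7)]}
        )
        out, gaps = fill_misses(t)
        assert gaps == []
        row = out[(out["frame"] == 1) & (out["id"] == 2)].iloc[0]
        assert (row["cx_px"], row["cy_px"]) == (9.0, 9.0)
        assert row["filled"] == 1
        # real records untouched
        real = out[out["filled"] == 0].reset_index(drop=True)
        pd.testing.assert_frame_equal(real, t)

    def test_long_gap_reported_not_filled(self):
        traj = [(0.0, 0.0)] + [None] * 100 + [(5.0, 5.0)]
        t = table_from_positions({0: [(1, 1)] * 102, 1: traj})
        out, gaps = fill_misses(t, CorrectionParams(max_gap=60))
        assert len(gaps) == 1
        assert (gaps[0].animal_id, gaps[0].start_frame, gaps[0].length) == (1, 1, 100)
        assert len(out[out["id"] == 1]) == 2

    def test_every_frame_complete_after_filling(self):
        t = table_from_positions(
            {0: [(0, 0), None, None, (3, 3)], 1: [(5, 5), (6, 6), None, (8, 8)]}
        )
        out, _ = fill_misses(t)
        assert (out.groupby("frame").size() == 2).all()

    @given(
        st.sets(st.tuples(st.integers(1, 20), st.integers(0, 2)), max_size=12)
    )
    def test_filling_preserves_real_records(self, holes):
        rng = np.random.default_rng(0)
        traj = {i: [(float(f * 3 + i), float(i * 10)) for f in range(22)] for i in range(3)}
        for f, i in holes:
            traj[i][f] = None
        t = table_from_positions(traj)
        out, gaps = fill_misses(t)
        real = out[out["filled"] == 0].reset_index(drop=True)
        pd.testing.assert_frame_equal(real, t)
        assert gaps == []
        assert (out.groupby("frame").size() == 3).all()


class TestDetectWarnings:
    def test_stationary_mice_emit_no_warnings(self):
        t = table_from_positions({0: [(0, 0)] * 5, 1: [(50, 50)] * 5})
        assert detect_warnings(t) == []

    def test_single_mouse_never_warns(self):
        t = table_from_positions({0: [(i * 30.0, 0) for i in range(5)]})
        assert detect_warnings(t) == []

    def test_positional_exchange_warns_both_ids_at_event_frame(self):
        a = [(0.0, 0.0)] * 5 + [(100.0, 0.0)] * 3
        b = [(100.0, 0.0)] * 5 + [(0.0, 0.0)] * 3
        t = table_from_positions({0: a, 1: b})
        warnings = detect_warnings(t)
        assert [(w.frame_index, w.animal_id) for w in warnings] == [(5, 0), (5, 1)]
        w = warnings[0]
        assert w.dist_min == 0.0 and w.dist_same == 100.0 and w.nearest_other_id == 1
        marked = mark_warnings(t, warnings)
        assert marked[(marked["frame"] == 5)]["warned"].tolist() == [1, 1]

    def test_small_own_moves_emit_no_warning(self):
        t = table_from_positions({0: [(0, 0), (10, 0)], 1: [(40, 0), (41, 0)]})
        assert detect_warnings(t) == []

    def test_exact_tie_emits_no_warning(self):
        # ID0's own move is 5; ID1's new position is also exactly 5 away
        t2 = table_from_positions({0: [(0, 0), (5, 0)], 1: [(20, 0), (-5, 0)]})
        assert all(w.animal_id != 0 for w in detect_warnings(t2))


class TestApplySwaps:
    def test_empty_directives_identity(self):
        t = table_from_positions({0: [(0, 0), (1, 1)], 1: [(5, 5), (6, 6)]})
        out, failures = apply_swaps(t, [])
        pd.testing.assert_frame_equal(out, t)
        assert failures == []

    def test_double_swap_is_identity(self):
        t = table_from_positions({0: [(i, 0.0) for i in range(20)],
                                  1: [(i, 50.0) for i in range(20)]})
        d = SwapDirective(10, 0, 1)
        once, _ = apply_swaps(t, [d])
        twice, _ = apply_swaps(once, [d])
        pd.testing.assert_frame_equal(twice, t)
        # and the single swap really exchanged the tail
        tail = once[(once["frame"] >= 10) & (once["id"] == 0)]
        assert (tail["cy_px"] == 50.0).all()

    def test_invalid_directives_skipped_but_valid_applied(self):
        t = table_from_positions({0: [(0, 0)] * 6, 1: [(5, 5)] * 6})
        good = SwapDirective(3, 0, 1)
        bad_id = SwapDirective(2, 0, 9)
        bad_frame = SwapDirective(99, 0, 1)
        out, failures = apply_swaps(t, [bad_id, good, bad_frame])
        assert len(failures) == 2
        assert (out[(out["frame"] >= 3) & (out["id"] == 0)]["cx_px"] == 5.0).all()

    def test_same_id_directive_rejected_at_construction(self):
        with pytest.raises(ValueError):
            SwapDirective(0, 1, 1)
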