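"""Row profiling, first-peak detection, change point, row/column cuts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greenrow.rowprofile import (
    NoOverlapError,
    NoPeakError,
    WidthSeries,
    column_cut,
    detect_overlap_changepoint,
    find_first_peak,
    peak_width_series,
    row_proportions,
    rowcut_foreground,
)

# ---------------------------------------------------------------------------
# independent oracles


def oracle_first_peak(profile, boundary_frac=0.05, min_peak_frac=0.1):
    """Set-based reformulation of the first-peak definition."""
    p = np.asarray(profile, dtype=float)
    n = p.size
    gmax = p.max()
    best = None
    for i in range(n):
        j = i
        while j + 1 < n and p[j + 1] == p[i]:
            j += 1
        if (
            p[i] > 0
            and (i == 0 or p[i - 1] < p[i])
            and (j == n - 1 or p[j + 1] < p[i])
            and p[i] >= min_peak_frac * gmax
        ):
            best = i
            break
    if best is None:
        raise NoPeakError
    thr = boundary_frac * p[best]
    below = [k for k in range(best) if p[k] < thr]
    above = [k for k in range(best + 1, n) if p[k] < thr]
    return (max(below) if below else 0, min(above) if above else n - 1)


def oracle_mean_shift(values, min_jump):
    """Exhaustive least-squares single-split search."""
    x = np.asarray(values, dtype=float)
    n = x.size
    sse0 = ((x - x.mean()) ** 2).sum()
    best_s, best_sse = None, np.inf
    for s in range(1, n):
        sse = ((x[:s] - x[:s].mean()) ** 2).sum() + (
            (x[s:] - x[s:].mean()) ** 2
        ).sum()
        if sse < best_sse - 1e-12:
            best_s, best_sse = s, sse
    if x[best_s:].mean() - x[:best_s].mean() < min_jump:
        raise NoOverlapError
    return best_s + 1, sse0 - best_sse  # 1-based first post-change frame


# ---------------------------------------------------------------------------


class TestRowProportions:
    def test_all_ones(self):
        assert np.allclose(row_proportions(np.ones((4, 5))), 1.0)

    def test_direct_count(self):
        mask = np.zeros((3, 4))
        mask[2, :2] = 1  # bottom image row -> bottom-up index 0
        prof = row_proportions(mask)
        assert prof[0] == 0.5 and prof[1] == 0 and prof[2] == 0

    def test_counting_oracle(self, rng):
        mask = rng.integers(0, 2, (13, 7))
        prof = row_proportions(mask)
        for i in range(13):
            assert prof[i] == mask[12 - i].sum() / 7


class TestFirstPeak:
    def test_spec_profile(self):
        prof = [0.0, 0.2, 0.6, 1.0, 0.6, 0.2, 0.04, 0.0]
        b = find_first_peak(prof)
        assert (b.peak_max, b.center_row) == (1.0, 3)
        assert (b.lower_row, b.upper_row, b.width) == (0, 6, 6)

    def test_single_spike(self):
        b = find_first_peak([0, 1, 0, 0])
        assert (b.lower_row, b.upper_row, b.width) == (0, 2, 2)

    def test_valley_not_crossed(self):
        # two peaks with an exact-zero valley: bounds stay on the first peak
        prof = [0, 0.6, 0.6, 0, 0, 1.0, 0]
        b = find_first_peak(prof)
        assert b.center_row == 1 and b.upper_row == 3

    def test_all_zero_raises(self):
        with pytest.raises(NoPeakError):
            find_first_peak([0.0, 0.0, 0.0])

    @settings(deadline=None, max_examples=400, derandomize=True)
    @given(
        st.lists(
            st.sampled_from([0.0, 0.04, 0.2, 0.6, 1.0]),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_oracle(self, profile):
        if max(profile) == 0:
            return
        bounds = find_first_peak(profile)
        lo, hi = oracle_first_peak(profile)
        assert (bounds.lower_row, bounds.upper_row) == (lo, hi)
        assert bounds.lower_row <= bounds.center_row <= bounds.upper_row


class TestWidthSeries:
    def test_constant_masks(self):
        mask = np.zeros((6, 6))
        mask[4:6] = 1
        ws = peak_width_series([mask] * 4)
        assert np.all(ws.widths == ws.widths[0])

    def test_empty_frames_missing(self):
        empty, full = np.zeros((6, 6)), np.ones((6, 6))
        ws = peak_width_series([empty, empty, full])
        assert np.isnan(ws.widths[:2]).all() and not np.isnan(ws.widths[2])

    def test_timestamps_must_increase(self):
        with pytest.raises(ValueError):
            WidthSeries(np.array([0.0, 0.0]), np.array([1.0, 2.0]))


class TestChangePoint:
    def test_clean_step(self):
        ws = WidthSeries(np.arange(20.0), np.array([5.0] * 10 + [15.0] * 10))
        cp = detect_overlap_changepoint(ws, min_jump=5)
        assert cp.frame_index == 11
        assert cp.pre_mean == 5 and cp.post_mean == 15

    def test_constant_series(self):
        ws = WidthSeries(np.arange(10.0), np.full(10, 7.0))
        with pytest.raises(NoOverlapError):
            detect_overlap_changepoint(ws, min_jump=1)

    def test_too_few_observations(self):
        ws = WidthSeries(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="at least 8"):
            detect_overlap_changepoint(ws)

    def test_missing_dropped(self):
        w = np.array([np.nan, 5, 5, 5, 5, np.nan, 5, 5, 15, 15, 15, 15])
        ws = WidthSeries(np.arange(12.0), w)
        cp = detect_overlap_changepoint(ws, min_jump=5)
        assert cp.frame_index == 9  # position in the full series

    def test_daily_median_smoothing(self):
        # 4 observations per day; one spike per pre-day does not trigger
        t = np.arange(32) / 4.0
        w = np.array(([5.0, 5, 50, 5] * 4) + ([30.0] * 16))
        cp = detect_overlap_changepoint(WidthSeries(t, w), min_jump=10)
        assert cp.frame_index == 17

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(
        st.lists(
            st.floats(0, 100, allow_nan=False), min_size=8, max_size=50
        )
    )
    def test_matches_exhaustive_oracle(self, values):
        ws = WidthSeries(np.arange(len(values), dtype=float), np.array(values))
        try:
            expected = oracle_mean_shift(values, min_jump=0.5)
        except NoOverlapError:
            with pytest.raises(NoOverlapError):
                detect_overlap_changepoint(ws, min_jump=0.5)
            return
        cp = detect_overlap_changepoint(ws, min_jump=0.5)
        assert cp.frame_index == expected[0]
        assert cp.score == pytest.approx(expected[1], abs=1e-6)


class TestCuts:
    def test_rowcut_band(self, small_scene):
        """Pre-overlap row-cut retains exactly the true foreground."""
        truth = small_scene["truth"]
        f = truth.overlap_frame - 3
        mask = small_scene["masks"][f - 1]
        bounds = find_first_peak(row_proportions(mask))
        fg = rowcut_foreground(mask, bounds) > 0
        tr = truth.fg_masks[f - 1]
        assert (fg & tr).sum() / (fg | tr).sum() >= 0.95

    def test_rowcut_full_range_is_identity(self):
        mask = np.random.default_rng(3).integers(0, 2, (8, 8))
        from greenrow.rowprofile import PeakBounds

        bounds = PeakBounds(0, 7, 3, 1.0)
        assert np.array_equal(rowcut_foreground(mask, bounds), mask)

    def test_column_cut_two_blobs(self):
        mask = np.zeros((10, 20))
        mask[:, 2:6] = 1
        mask[:, 12:17] = 1
        assert column_cut(mask) == [(2, 5), (12, 16)]

    def test_column_cut_single_blob(self):
        mask = np.zeros((5, 9))
        mask[:, 3:6] = 1
        assert column_cut(mask) == [(3, 5)]

    def test_column_cut_six_plants(self):
        from greenrow.synthfield import SynthFieldConfig, generate_field_sequence

        cfg = SynthFieldConfig(n_plants=6, n_bg_plants=0, seed=11)
        frames, truth = generate_field_sequence(cfg)
        # last frame in which the 6 true silhouettes are still separated by
        # empty columns (late frames have touching leaves: a single blob)
        mask = None
        for fg in reversed(truth.fg_masks):
            cols = fg.any(axis=0)
            runs = np.diff(np.concatenate([[0], cols, [0]])) == 1
            if runs.sum() == 6:
                mask = fg
                break
        assert mask is not None
        intervals = column_cut(mask, max_plants=6)
        assert len(intervals) == 6
        # each detected interval sits in a distinct true plant slot
        slots = set()
        for a, b in intervals:
            mid = (a + b) / 2
            hit = [
                p
                for p, (ta, tb) in enumerate(truth.plant_intervals)
                if ta <= mid <= tb
            ]
            assert len(hit) == 1
            slots.add(hit[0])
        assert len(slots) == 6
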