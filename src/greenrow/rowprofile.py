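"""Row-proportion profiling and the row-cut / column-cut algorithms.

For each segmented frame, the proportion of plant pixels in every image row is
computed, scanning **from the bottom of the image up** (the foreground plant
row is nearest the camera and therefore lowest in the image).  The first peak
of this profile locates the foreground plants; the width of that peak, tracked
over the frame sequence, jumps sharply on the day the foreground silhouettes
start to merge with the taller-appearing background row — a single mean-shift
change point on the width series estimates that overlap time.

Indexing conventions
--------------------
* Row profiles and ``PeakBounds`` use *bottom-up* row indices: index 0 is the
  bottom image row.  :func:`bottomup_to_image_row` is the single conversion
  point to top-down image coordinates.
* ``ChangePoint.frame_index`` counts frames **from 1** (the convention of the
  change-point literature): it is the 1-based position of the first
  post-overlap frame in the width series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class NoPeakError(ValueError):
    """The row profile contains no usable peak (e.g. an empty mask)."""


class NoOverlapError(ValueError):
    """No mean shift of at least ``min_jump`` exists in the width series."""


def bottomup_to_image_row(row: int, n_rows: int) -> int:
    """Convert a bottom-up row index to a top-down image row index."""
    return n_rows - 1 - row


@dataclass(frozen=True)
class PeakBounds:
    """Bounds of one peak of a row (or column) profile, bottom-up indices."""

    lower_row: int
    upper_row: int
    center_row: int
    peak_max: float

    def __post_init__(self):
        if not self.lower_row <= self.center_row <= self.upper_row:
            raise ValueError("peak center must lie within its bounds")

    @property
    def width(self) -> int:
        return self.upper_row - self.lower_row


@dataclass(frozen=True)
class WidthSeries:
    """First-peak width per frame; frames with no detectable peak are NaN."""

    timestamps: np.ndarray
    widths: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.timestamps, dtype=np.float64)
        w = np.asarray(self.widths, dtype=np.float64)
        if t.shape != w.shape or t.ndim != 1:
            raise ValueError("timestamps and widths must be equal-length 1-d")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "widths", w)

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class ChangePoint:
    """A single mean-shift change point in a width series.

    ``frame_index`` is the 1-based position of the first post-overlap frame;
    ``score`` is the SSE reduction achieved by the fitted split.
    """

    frame_index: int
    score: float
    pre_mean: float = field(default=np.nan)
    post_mean: float = field(default=np.nan)


def row_proportions(mask: np.ndarray) -> np.ndarray:
    """Per-row proportion of plant pixels, bottom-up (index 0 = bottom row)."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a nonempty 2-d array")
    return (mask > 0).mean(axis=1)[::-1]


def column_proportions(mask: np.ndarray) -> np.ndarray:
    """Per-column proportion of plant pixels (left to right)."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.size == 0:
        raise ValueError("mask must be a nonempty 2-d array")
    return (mask > 0).mean(axis=0)


def _local_max_plateaus(profile: np.ndarray):
    """Yield (start, stop_inclusive, value) for strict local-max plateaus."""
    n = profile.size
    i = 0
    while i < n:
        j = i
        while j + 1 < n and profile[j + 1] == profile[i]:
            j += 1
        v = profile[i]
        left_ok = i == 0 or profile[i - 1] < v
        right_ok = j == n - 1 or profile[j + 1] < v
        if v > 0 and left_ok and right_ok:
            yield i, j, float(v)
        i = j + 1


def find_first_peak(
    profile: np.ndarray,
    boundary_frac: float = 0.05,
    min_peak_frac: float = 0.1,
) -> PeakBounds:
    """Locate the first (lowest) peak of a bottom-up row profile.

    Scanning from the bottom, the first local-maximum plateau whose height is
    at least ``min_peak_frac`` of the global maximum is taken as the peak; its
    bottom-most maximal row is the center.  The lower (upper) boundary is the
    first row below (above) the center whose value drops under
    ``boundary_frac`` times the peak maximum, or the profile end if none does.

    ``min_peak_frac`` suppresses noise bumps below the foreground plants; set
    it to 0 to accept any local maximum.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 1 or profile.size == 0:
        raise ValueError("profile must be a nonempty 1-d array")
    gmax = profile.max()
    if gmax <= 0:
        raise NoPeakError("profile is all zero: no peak")
    peak = None
    for i, j, v in _local_max_plateaus(profile):
        if v >= min_peak_frac * gmax:
            peak = (i, v)
            break
    if peak is None:  # pragma: no cover - gmax>0 guarantees a plateau
        raise NoPeakError("no qualifying peak")
    center, peak_max = peak
    thr = boundary_frac * peak_max
    lower = 0
    for k in range(center - 1, -1, -1):
        if profile[k] < thr:
            lower = k
            break
    upper = profile.size - 1
    for k in range(center + 1, profile.size):
        if profile[k] < thr:
            upper = k
            break
    return PeakBounds(lower, upper, center, peak_max)


def peak_width_series(
    masks,
    timestamps=None,
    boundary_frac: float = 0.05,
    min_peak_frac: float = 0.1,
) -> WidthSeries:
    """First-peak width for each frame of an ordered mask sequence.

    Frames whose profile has no usable peak are recorded as NaN widths.
    """
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    if timestamps is None:
        timestamps = np.arange(len(masks), dtype=np.float64)
    widths = np.full(len(masks), np.nan)
    for f, mask in enumerate(masks):
        try:
            widths[f] = find_first_peak(
                row_proportions(mask), boundary_frac, min_peak_frac
            ).width
        except NoPeakError:
            pass
    return WidthSeries(np.asarray(timestamps, dtype=np.float64), widths)


def _best_mean_shift_split(values: np.ndarray):
    """Least-squares single mean-shift fit: returns (split, score).

    ``split`` is the 0-based index of the first element of the second segment
    among all splits 1..n-1, chosen to minimise the total within-segment SSE;
    ``score`` is the SSE reduction relative to the no-split fit.  Ties go to
    the earliest split.
    """
    n = values.size
    # prefix sums give O(n) SSE for every split
    s1 = np.concatenate([[0.0], np.cumsum(values)])
    s2 = np.concatenate([[0.0], np.cumsum(values**2)])

    def sse(a, b):  # [a, b)
        m = b - a
        tot, tot2 = s1[b] - s1[a], s2[b] - s2[a]
        return tot2 - tot * tot / m

    total = sse(0, n)
    splits = np.arange(1, n)
    costs = np.array([sse(0, s) + sse(s, n) for s in splits])
    best = int(np.argmin(costs))
    return int(splits[best]), float(total - costs[best])


class MeanShiftChangePoint:
    """Single mean-shift change-point detector for first-peak width series.

    After collapsing the series to per-day medians (``day_length`` timestamp
    units per day; with the default 1.0 and integer frame timestamps this is
    the identity), the split minimising the total within-segment sum of
    squared errors over all split positions is fitted.  A change point is
    reported only if the post-split mean exceeds the pre-split mean by at
    least ``min_jump`` rows — the overlap of foreground and background
    silhouettes always *widens* the first peak.

    Attributes (after :meth:`fit`)
    ------------------------------
    change_point_ : ChangePoint
    day_medians_ : ndarray, the smoothed series the split was fitted on
    """

    def __init__(self, min_jump: float = 20.0, day_length: float = 1.0):
        self.min_jump = min_jump
        self.day_length = day_length

    def get_params(self, deep=True):
        return {"min_jump": self.min_jump, "day_length": self.day_length}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, series: WidthSeries):
        ok = ~np.isnan(series.widths)
        t, w = series.timestamps[ok], series.widths[ok]
        if w.size < 8:
            raise ValueError(
                f"need at least 8 non-missing widths, got {w.size}"
            )
        days = np.floor(t / self.day_length)
        uniq, inverse = np.unique(days, return_inverse=True)
        med = np.array([np.median(w[inverse == d]) for d in range(uniq.size)])
        if uniq.size < 2:
            raise NoOverlapError("need at least 2 days of observations")
        split, score = _best_mean_shift_split(med)
        pre, post = med[:split].mean(), med[split:].mean()
        if post - pre < self.min_jump:
            raise NoOverlapError(
                f"no overlap detected: best jump {post - pre:.2f} rows "
                f"< min_jump {self.min_jump}"
            )
        # first frame of the first post-change day, as a 1-based position in
        # the full (missing included) series
        first_t = t[inverse == split][0]
        frame_index = int(np.flatnonzero(series.timestamps == first_t)[0]) + 1
        self.day_medians_ = med
        self.change_point_ = ChangePoint(frame_index, score, pre, post)
        return self

    def fit_predict(self, series: WidthSeries) -> ChangePoint:
        return self.fit(series).change_point_


def detect_overlap_changepoint(
    series: WidthSeries, min_jump: float = 20.0, day_length: float = 1.0
) -> ChangePoint:
    """Estimate the first post-overlap frame from a first-peak width series."""
    return MeanShiftChangePoint(min_jump, day_length).fit_predict(series)


def rowcut_foreground(mask: np.ndarray, bounds: PeakBounds) -> np.ndarray:
    """Zero all plant pixels outside the first-peak row band (the row-cut)."""
    mask = np.asarray(mask)
    n_rows = mask.shape[0]
    out = np.zeros_like(mask)
    top = bottomup_to_image_row(bounds.upper_row, n_rows)
    bottom = bottomup_to_image_row(bounds.lower_row, n_rows)
    out[top : bottom + 1] = mask[top : bottom + 1]
    return out


def column_cut(
    fg_mask: np.ndarray, max_plants: int = 6, valley_frac: float = 0.05
):
    """Split a foreground mask into per-plant column intervals (column-cut).

    The per-column plant-pixel proportion profile is thresholded at
    ``valley_frac`` times its maximum; maximal runs of columns at or above the
    threshold become intervals (each necessarily containing a column-profile
    peak).  If more than ``max_plants`` runs survive, the ``max_plants`` with
    the largest plant-pixel mass are kept.

    Returns a list of ``(start_col, end_col)`` tuples, end inclusive, in
    left-to-right order.
    """
    prof = column_proportions(fg_mask)
    if prof.max() <= 0:
        raise ValueError("foreground mask has no plant pixels")
    above = prof >= valley_frac * prof.max()
    intervals = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above, [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        intervals.append((int(start), int(stop) - 1))
    if len(intervals) > max_plants:
        mass = [prof[a : b + 1].sum() for a, b in intervals]
        keep = sorted(np.argsort(mass)[-max_plants:])
        intervals = [intervals[i] for i in keep]
    return intervals
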