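"""Per-plant height measurement from segmented foreground masks.

Early (pre-overlap) frames: the row-cut band and the column-cut intervals
isolate each foreground plant directly, and its height is the inclusive pixel
span between its top-most and bottom-most plant pixel.  Late (post-overlap)
frames work on the CNN-refined foreground mask instead: the bottom-up
row-mean curve is LOESS-smoothed, the foreground row band is bounded at the
first rows falling under 7.5% (above the peak) and 2.5% (below) of the
smoothed maximum, and the same column-cut and top/bottom measurement is
applied within the band.

Heights are reported in pixels; an optional pinhole-camera conversion to
centimetres uses the camera's focal length, sensor size and row distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .rowprofile import (
    NoPeakError,
    PeakBounds,
    bottomup_to_image_row,
    column_cut,
    row_proportions,
    rowcut_foreground,
)


@dataclass(frozen=True)
class CameraCalibration:
    """Pinhole-model constants of the row camera (defaults: NIKON COOLPIX
    S3700 at 213.4 cm from the plant row)."""

    focal_mm: float = 4.5
    sensor_w_mm: float = 6.17
    sensor_h_mm: float = 4.55
    distance_cm: float = 213.4

    def __post_init__(self):
        if min(
            self.focal_mm, self.sensor_w_mm, self.sensor_h_mm, self.distance_cm
        ) <= 0:
            raise ValueError("all calibration constants must be positive")


@dataclass(frozen=True)
class HeightObservation:
    """One plant-height measurement from one frame."""

    plant: int
    timestamp: float
    height_px: float
    stage: str  # "early" | "late"
    camera: str = ""


def measure_height_early(fg_mask: np.ndarray, interval) -> int:
    """Height (pixels, inclusive) of the plant inside a column interval.

    ``interval`` is a ``(start_col, end_col)`` pair, end inclusive.  Raises
    ``ValueError`` when the interval contains no plant pixel (the observation
    is missing).
    """
    fg_mask = np.asarray(fg_mask)
    start, end = interval
    rows = np.flatnonzero((fg_mask[:, start : end + 1] > 0).any(axis=1))
    if rows.size == 0:
        raise ValueError("column interval contains no plant pixels")
    return int(rows.max() - rows.min() + 1)


def smooth_row_means(
    refined_mask: np.ndarray, span: float = 0.1
) -> np.ndarray:
    """LOESS-smoothed bottom-up row-mean curve of a foreground mask.

    Local linear smoothing (``span`` = fraction of rows per window, no
    robustness iterations) reproduces linear trends exactly; the result is
    clipped at 0 since row means are proportions.
    """
    values = row_proportions(refined_mask)
    n = values.size
    if n < 3 or span <= 0:
        return values.copy()
    smoothed = sm.nonparametric.lowess(
        values,
        np.arange(n, dtype=np.float64),
        frac=min(max(span, 3.0 / n), 1.0),
        it=0,
        return_sorted=False,
    )
    return np.clip(smoothed, 0.0, None)


def locate_foreground_rows(
    smoothed: np.ndarray,
    upper_frac: float = 0.075,
    lower_frac: float = 0.025,
) -> PeakBounds:
    """Bound the foreground row band from a smoothed row-mean curve.

    From the curve maximum (ties toward the bottom), the upper boundary is
    the first row above with a value below ``upper_frac`` of the maximum and
    the lower boundary the first row below with a value under ``lower_frac``
    of it; a missing crossing extends the bound to the profile end.
    """
    smoothed = np.asarray(smoothed, dtype=np.float64)
    peak_max = smoothed.max()
    if peak_max <= 0:
        raise NoPeakError("smoothed row means are all zero")
    center = int(np.argmax(smoothed))
    upper = smoothed.size - 1
    for k in range(center + 1, smoothed.size):
        if smoothed[k] < upper_frac * peak_max:
            upper = k
            break
    lower = 0
    for k in range(center - 1, -1, -1):
        if smoothed[k] < lower_frac * peak_max:
            lower = k
            break
    return PeakBounds(lower, upper, center, float(peak_max))


def measure_heights_late(
    refined_mask: np.ndarray,
    max_plants: int = 6,
    span: float = 0.1,
    upper_frac: float = 0.075,
    lower_frac: float = 0.025,
    valley_frac: float = 0.05,
):
    """Per-plant heights from a refined (post-overlap) foreground mask.

    Returns a list of ``(interval, height_px)`` pairs in left-to-right order;
    empty when the mask holds no plants.
    """
    refined_mask = np.asarray(refined_mask)
    if not (refined_mask > 0).any():
        return []
    bounds = locate_foreground_rows(
        smooth_row_means(refined_mask, span), upper_frac, lower_frac
    )
    banded = rowcut_foreground(refined_mask, bounds)
    if not (banded > 0).any():
        return []
    intervals = column_cut(banded, max_plants, valley_frac)
    out = []
    for interval in intervals:
        try:
            out.append((interval, measure_height_early(banded, interval)))
        except ValueError:
            continue
    return out


def pixels_to_cm(
    height_px: float,
    calib: CameraCalibration = CameraCalibration(),
    working_rows: int = 750,
) -> float:
    """Convert a pixel height to centimetres with the pinhole model.

    One pixel row spans ``sensor_h_mm / working_rows`` on the sensor, which
    back-projects through the focal length to
    ``distance / focal`` times that at the plant row.
    """
    if working_rows <= 0:
        raise ValueError("working_rows must be positive")
    mm_per_row = calib.sensor_h_mm / working_rows
    scale = (calib.distance_cm * 10.0) / calib.focal_mm  # object/image ratio
    return height_px * mm_per_row * scale / 10.0
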