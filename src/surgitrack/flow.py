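"""Hemorrhage flow analysis from the per-frame blood-area series.

The detected blood area (pixel count per frame) is smoothed with a moving
median, a piecewise-linear *trend* is drawn through its local extrema, and
sliding windows are classified by the mean trend slope:

* slope > threshold        → flowing, warning raised;
* |slope| <= threshold     → stagnant, no warning;
* slope < −threshold       → stagnant (bleed being stanched), no warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .regions import Detection

__all__ = ["AreaSeries", "FlowWindow", "area_series", "trend_line", "classify_flow"]


@dataclass
class AreaSeries:
    """Per-frame hemorrhage area plus derived trend/classification."""

    frames: np.ndarray
    area_px: np.ndarray
    trend: np.ndarray | None = None
    windows: list["FlowWindow"] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.area_px = np.asarray(self.area_px, dtype=float)
        if np.any(self.area_px < 0):
            raise ValueError("areas must be non-negative")


@dataclass
class FlowWindow:
    """Classification of one sliding window of the area series."""

    start: int
    end: int  # inclusive frame index
    slope: float  # mean trend slope, px^2 per frame
    label: str  # "flowing" | "stagnant"
    warning: bool


def area_series(
    fused_per_frame: Sequence[Sequence[Detection]], kind: str = "hemorrhage"
) -> AreaSeries:
    """Total detected area of ``kind`` per frame (0 where absent)."""
    areas = []
    for dets in fused_per_frame:
        areas.append(float(sum(d.area_px for d in dets if d.kind == kind)))
    return AreaSeries(frames=np.arange(len(areas)), area_px=np.array(areas))


def _smooth(series: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return series.astype(float)
    return ndimage.median_filter(series.astype(float), size=window, mode="nearest")


def trend_line(series: AreaSeries, smooth_window: int = 5) -> np.ndarray:
    """Piecewise-linear envelope through local extrema of the smoothed series.

    Endpoints are anchored at the first/last smoothed values; a constant
    series yields a flat trend, a monotone ramp a single segment.
    """
    a = _smooth(series.area_px, smooth_window)
    n = len(a)
    if n == 0:
        return np.array([])
    if n < 3:
        return a.copy()
    d = np.diff(a)
    knots = [0]
    for i in range(1, n - 1):
        left = d[i - 1]
        right = d[i]
        if (left > 0 >= right) or (left < 0 <= right):
            if left != 0 or right != 0:  # skip interior of plateaus
                knots.append(i)
    knots.append(n - 1)
    knots = sorted(set(knots))
    return np.interp(np.arange(n), knots, a[knots])


def classify_flow(
    series: AreaSeries,
    window_frames: int = 30,
    slope_threshold: float = 10.0,
    smooth_window: int = 5,
    stride: int = 1,
) -> AreaSeries:
    """Classify sliding windows of the area series as flowing or stagnant.

    ``slope_threshold`` is in area pixels per frame.  Returns the series
    with ``trend`` and ``windows`` filled in.
    """
    trend = trend_line(series, smooth_window)
    series.trend = trend
    series.windows = []
    n = len(trend)
    if n == 0:
        return series
    if n <= window_frames:
        spans = [(0, n - 1)]
    else:
        spans = [(s, s + window_frames - 1) for s in range(0, n - window_frames + 1, stride)]
    for s, e in spans:
        slope = (trend[e] - trend[s]) / max(e - s, 1)
        if slope > slope_threshold:
            series.windows.append(FlowWindow(s, e, float(slope), "flowing", True))
        else:
            series.windows.append(FlowWindow(s, e, float(slope), "stagnant", False))
    return series
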