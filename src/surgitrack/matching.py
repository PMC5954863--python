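"""Template matching by minimum sum-of-squared differences (SSD).

The dissimilarity between a candidate image f and a template t is

    d(u, v) = sum_{x,y} ( f(x+u, y+v) - t(x, y) )^2

over all placements where the template lies fully inside the candidate.
Expanding the square gives d = S_f2(u,v) - 2 (f ⋆ t)(u,v) + sum(t^2): the
cross term is computed by FFT convolution and the per-window sum of f^2 by a
summed-area table, so the full map costs O(N log N) instead of O(N·M).

The matching template is the pixel-wise mean of the object's accepted
appearance crops over a rolling 0.5 s window (the template buffer).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Deque

import math

import numpy as np
from scipy.signal import fftconvolve

from .regions import Detection

__all__ = ["TemplateBuffer", "update_template", "ssd_map", "match", "extract_crop"]


@dataclass
class TemplateBuffer:
    """Rolling buffer of grayscale appearance crops for one tracked object.

    Capacity is ``ceil(window_s * fps)`` crops (0.5 s at 10 fps → 5); the
    template is the pixel-wise mean of the stored crops and is defined iff
    the buffer is non-empty.
    """

    shape: tuple[int, int]  # (h, w) of every crop
    window_s: float = 0.5
    fps: float = 10.0
    crops: Deque[np.ndarray] = field(default_factory=deque)

    @property
    def capacity(self) -> int:
        return max(1, math.ceil(self.window_s * self.fps))

    @property
    def template(self) -> np.ndarray | None:
        if not self.crops:
            return None
        return np.mean(np.stack(self.crops), axis=0)


def update_template(buffer: TemplateBuffer, crop: np.ndarray) -> TemplateBuffer:
    """Append a crop (evicting the oldest when over capacity); returns buffer."""
    crop = np.asarray(crop, dtype=float)
    if crop.shape != buffer.shape:
        raise ValueError(
            f"crop shape {crop.shape} does not match template shape {buffer.shape}"
        )
    buffer.crops.append(crop)
    while len(buffer.crops) > buffer.capacity:
        buffer.crops.popleft()
    return buffer


def ssd_map(f: np.ndarray, t: np.ndarray) -> np.ndarray:
    """SSD of template t against every full-overlap placement in f.

    Returns a ``(H-h+1, W-w+1)`` map indexed by the placement of the
    template's top-left corner, clamped at 0 against FFT round-off.
    """
    f = np.asarray(f, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    if t.shape[0] > f.shape[0] or t.shape[1] > f.shape[1]:
        raise ValueError(f"template {t.shape} larger than candidate {f.shape}")
    corr = fftconvolve(f, t[::-1, ::-1], mode="valid")
    win_f2 = _window_sums(f * f, t.shape)
    d = win_f2 - 2.0 * corr + float((t * t).sum())
    return np.maximum(d, 0.0)


def _window_sums(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Sliding-window sums of ``a`` over windows of ``shape`` (summed-area table)."""
    h, w = shape
    S = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    S[1:, 1:] = a.cumsum(axis=0).cumsum(axis=1)
    return S[h:, w:] - S[:-h, w:] - S[h:, :-w] + S[:-h, :-w]


def extract_crop(
    gray: np.ndarray, center_xy: tuple[float, float], shape: tuple[int, int]
) -> np.ndarray:
    """Fixed-size grayscale crop centred at (x, y), edge-padded at borders."""
    h, w = shape
    cx, cy = center_xy
    r0 = int(round(cy - (h - 1) / 2.0))
    c0 = int(round(cx - (w - 1) / 2.0))
    pr0, pc0 = max(0, -r0), max(0, -c0)
    r0, c0 = max(0, r0), max(0, c0)
    r1, c1 = min(gray.shape[0], r0 + h - pr0), min(gray.shape[1], c0 + w - pc0)
    crop = np.empty((h, w), dtype=float)
    inner = gray[r0:r1, c0:c1].astype(float)
    # edge-pad to the requested shape
    crop[:] = np.pad(
        inner,
        ((pr0, h - pr0 - inner.shape[0]), (pc0, w - pc0 - inner.shape[1])),
        mode="edge",
    )
    return crop


def match(
    candidate: np.ndarray,
    buffer: TemplateBuffer,
    search_center: tuple[float, float] | None = None,
    search_halfwidth: int | None = 48,
    prev_position: tuple[float, float] | None = None,
    frame_index: int = 0,
    kind: str = "hemorrhage",
) -> Detection | None:
    """Locate the buffer's template in a grayscale candidate image.

    Searches placements whose template centre lies within
    ``search_halfwidth`` of ``search_center`` (full-frame when no window is
    given).  Returns a Detection (source="template") at the argmin
    placement's template centre, or None when the buffer is empty.  Ties at
    the minimum are broken by distance to ``prev_position``, then by
    smallest (u, v) placement.
    """
    t = buffer.template
    if t is None:
        return None
    h, w = buffer.shape
    H, W = candidate.shape

    if search_center is not None and search_halfwidth is not None:
        cx, cy = search_center
        r0 = int(math.floor(cy - (h - 1) / 2.0 - search_halfwidth))
        c0 = int(math.floor(cx - (w - 1) / 2.0 - search_halfwidth))
        r1 = int(math.ceil(cy + (h - 1) / 2.0 + search_halfwidth)) + 1
        c0, r0 = max(0, c0), max(0, r0)
        c1 = int(math.ceil(cx + (w - 1) / 2.0 + search_halfwidth)) + 1
        r1, c1 = min(H, r1), min(W, c1)
        # guarantee the region can hold the template
        if r1 - r0 < h:
            r0, r1 = max(0, min(r0, H - h)), min(H, max(r1, h))
        if c1 - c0 < w:
            c0, c1 = max(0, min(c0, W - w)), min(W, max(c1, w))
        region = candidate[r0:r1, c0:c1]
        if region.shape[0] < h or region.shape[1] < w:
            return None
    else:
        r0 = c0 = 0
        region = candidate

    d = ssd_map(region, t)
    dmin = d.min()
    vs, us = np.nonzero(d <= dmin + 1e-9)  # v=row, u=col placements
    # template-centre coordinates of each tied placement (global frame coords)
    centers_x = us + c0 + (w - 1) / 2.0
    centers_y = vs + r0 + (h - 1) / 2.0
    if prev_position is not None and len(us) > 1:
        px, py = prev_position
        dist2 = (centers_x - px) ** 2 + (centers_y - py) ** 2
    else:
        dist2 = np.zeros(len(us))
    order = sorted(range(len(us)), key=lambda i: (dist2[i], us[i], vs[i]))
    best = order[0]
    cx_, cy_ = float(centers_x[best]), float(centers_y[best])
    x0, y0 = us[best] + c0, vs[best] + r0
    corners = np.array(
        [[x0, y0], [x0 + w - 1, y0], [x0 + w - 1, y0 + h - 1], [x0, y0 + h - 1]],
        dtype=float,
    )
    return Detection(
        kind=kind,
        centroid=(cx_, cy_),
        area_px=int(h * w),
        frame_index=frame_index,
        boundary=corners,
        source="template",
        score=float(dmin) / (h * w),  # mean per-pixel residual: match quality
    )
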