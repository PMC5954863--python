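"""Hemorrhage segmentation: contrast enhancement, mutually inclusive RGB
thresholding, entropy/edge-based mask refinement.

Pipeline order: per-channel histogram equalization → per-channel band
thresholds combined by logical AND ("mutually inclusive") → refinement
(local-entropy pruning, canny-assisted morphological closing, small-object
removal) → connected-component extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, feature, measure, morphology
from skimage.filters import rank

from .frame_io import Frame
from .regions import BinaryMask, Detection, mask_to_detections

__all__ = [
    "HemorrhageParams",
    "equalize_rgb",
    "mutually_inclusive_threshold",
    "refine_mask",
    "extract_detections",
    "segment_hemorrhage",
]


@dataclass
class HemorrhageParams:
    """Tunable parameters of the hemorrhage segmenter.

    Channel bounds apply to the equalized frame (0–255).  The entropy
    threshold is in bits over a square neighbourhood window; flat regions
    (e.g. saturated specular patches) fall below it and are pruned.
    """

    r_bounds: tuple[int, int] = (140, 255)
    g_bounds: tuple[int, int] = (0, 100)
    b_bounds: tuple[int, int] = (0, 100)
    entropy_min: float = 3.0
    entropy_window: int = 9
    canny_sigma: float = 1.0
    opening_radius: int = 1  # kills isolated threshold-noise pixels
    closing_radius: int = 2  # 5x5 disc
    min_area: int = 150  # below ~7 px radius is indistinguishable from noise


def equalize_rgb(frame: Frame) -> Frame:
    """Histogram-equalize each RGB channel independently over [0, 255]."""
    out = np.empty_like(frame.pixels)
    for c in range(3):
        ch = frame.pixels[..., c]
        if ch.min() == ch.max():  # degenerate histogram: constant stays constant
            out[..., c] = ch
            continue
        eq = exposure.equalize_hist(ch, nbins=256)
        out[..., c] = np.clip(np.round(eq * 255.0), 0, 255).astype(np.uint8)
    return Frame(index=frame.index, time_s=frame.time_s, pixels=out)


def mutually_inclusive_threshold(
    frame: Frame,
    r_bounds: tuple[int, int] = (140, 255),
    g_bounds: tuple[int, int] = (0, 100),
    b_bounds: tuple[int, int] = (0, 100),
) -> BinaryMask:
    """AND-combine per-channel band thresholds into a hemorrhage mask.

    A pixel is labelled only if it satisfies its (low, high) bound in every
    channel (bounds inclusive).
    """
    masks = []
    for c, (lo, hi) in enumerate((r_bounds, g_bounds, b_bounds)):
        if lo > hi:
            raise ValueError(f"channel {c}: low bound {lo} exceeds high bound {hi}")
        ch = frame.pixels[..., c]
        masks.append((ch >= lo) & (ch <= hi))
    return BinaryMask(masks[0] & masks[1] & masks[2], kind="hemorrhage")


def _luma(pixels: np.ndarray) -> np.ndarray:
    w = np.array([0.299, 0.587, 0.114])
    return np.clip(pixels.astype(float) @ w, 0, 255).astype(np.uint8)


def refine_mask(
    mask: BinaryMask | np.ndarray,
    frame: Frame,
    params: HemorrhageParams | None = None,
) -> BinaryMask:
    """Clean a candidate mask using local entropy, canny edges, and area.

    Steps: (0) a small opening removes isolated threshold-noise pixels;
    (i) prune mask pixels whose local entropy of the grayscale frame
    falls below ``entropy_min`` (suppresses flat specular regions);
    (ii) close contour gaps by morphological closing of the mask together
    with nearby canny edges; (iii) drop components below ``min_area``.
    The result never extends beyond the input mask dilated by the closing
    element.
    """
    params = params or HemorrhageParams()
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if data.shape != frame.pixels.shape[:2]:
        raise ValueError("mask and frame dimensions differ")

    if params.opening_radius > 0 and data.any():
        open_se = morphology.disk(params.opening_radius).astype(bool)
        data = ndimage.binary_opening(data, structure=open_se)
    if not data.any():
        return BinaryMask(data.copy(), kind="hemorrhage")

    selem = morphology.disk(params.closing_radius).astype(bool)
    allowed = ndimage.binary_dilation(data, structure=selem)

    # work on the bounding box of the allowed region for speed
    rows = np.nonzero(allowed.any(axis=1))[0]
    cols = np.nonzero(allowed.any(axis=0))[0]
    pad = params.entropy_window
    r0, r1 = max(0, rows[0] - pad), min(data.shape[0], rows[-1] + pad + 1)
    c0, c1 = max(0, cols[0] - pad), min(data.shape[1], cols[-1] + pad + 1)

    gray = _luma(frame.pixels[r0:r1, c0:c1])
    sub = data[r0:r1, c0:c1]
    sub_allowed = allowed[r0:r1, c0:c1]

    if params.entropy_min > 0:
        ent = rank.entropy(gray, np.ones((params.entropy_window,) * 2, dtype=bool))
        sub = sub & (ent >= params.entropy_min)

    edges = feature.canny(gray, sigma=params.canny_sigma)
    edges = edges & ndimage.binary_dilation(sub, structure=selem)
    closed = ndimage.binary_closing(sub | edges, structure=selem) & sub_allowed
    closed = _drop_small(closed, params.min_area)

    out = np.zeros_like(data)
    out[r0:r1, c0:c1] = closed
    return BinaryMask(out, kind="hemorrhage")


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove 8-connected components smaller than min_area."""
    if min_area <= 1 or not mask.any():
        return mask
    labeled = measure.label(mask, connectivity=2)
    counts = np.bincount(labeled.ravel())
    keep = counts >= min_area
    keep[0] = False
    return keep[labeled]


def extract_detections(
    mask: BinaryMask | np.ndarray, frame_index: int, min_area: int = 0
) -> list[Detection]:
    """One Detection per 8-connected component of the refined mask."""
    return mask_to_detections(
        mask, frame_index, kind="hemorrhage", min_area=min_area, source="segmentation"
    )


def segment_hemorrhage(
    frame: Frame, params: HemorrhageParams | None = None
) -> list[Detection]:
    """Full per-frame hemorrhage segmentation: equalize → AND-threshold →
    refine → extract."""
    params = params or HemorrhageParams()
    eq = equalize_rgb(frame)
    mask = mutually_inclusive_threshold(
        eq, params.r_bounds, params.g_bounds, params.b_bounds
    )
    refined = refine_mask(mask, frame, params)
    return extract_detections(refined, frame.index, min_area=params.min_area)
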