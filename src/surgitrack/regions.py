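"""Binary masks, detections, and mask→detection extraction.

The detection centroid is the *geometric centre* in the sense used for
surgical-video ground truth here: the per-axis median of the object's
boundary pixels, not the area centroid (the area centroid is also kept for
reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "BinaryMask",
    "Detection",
    "boundary_pixels",
    "geometric_center",
    "mask_to_detections",
]


@dataclass
class BinaryMask:
    """A boolean H×W mask with a kind tag (hemorrhage | instrument | motion)."""

    data: np.ndarray
    kind: str = "hemorrhage"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class Detection:
    """One segmented/matched object instance in one frame.

    centroid is (x, y); boundary is an (N, 2) array of (x, y) boundary
    pixels; area_px counts all pixels of the region, not just the boundary.
    source records which stage produced it: segmentation | template | fused.
    """

    kind: str
    centroid: tuple[float, float]
    area_px: int
    frame_index: int
    boundary: np.ndarray | None = None
    source: str = "segmentation"
    label: int | None = None
    area_centroid: tuple[float, float] | None = None
    score: float | None = None  # template matches: mean per-pixel SSD residual

    def __post_init__(self) -> None:
        self.centroid = (float(self.centroid[0]), float(self.centroid[1]))
        if self.boundary is not None:
            self.boundary = np.asarray(self.boundary, dtype=float)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Return (N, 2) array of (x, y) boundary pixels of a boolean mask.

    A pixel is a boundary pixel if it is on and at least one 4-neighbour
    (or the image border) is off.
    """
    mask = np.asarray(mask, dtype=bool)
    inner = ndimage.binary_erosion(mask, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool), border_value=0)
    edge = mask & ~inner
    ys, xs = np.nonzero(edge)
    return np.column_stack([xs, ys]).astype(float)


def geometric_center(boundary: np.ndarray) -> tuple[float, float]:
    """Per-axis median of boundary pixel coordinates; boundary is (N, 2) xy."""
    b = np.asarray(boundary, dtype=float)
    if b.size == 0:
        raise ValueError("empty boundary")
    return float(np.median(b[:, 0])), float(np.median(b[:, 1]))


def mask_to_detections(
    mask: BinaryMask | np.ndarray,
    frame_index: int,
    kind: str | None = None,
    min_area: int = 0,
    source: str = "segmentation",
) -> list[Detection]:
    """Split a mask into 8-connected components and build one Detection each.

    Components smaller than ``min_area`` are dropped.  Detections are
    returned sorted by (x, y) of their centroid for determinism.
    """
    if isinstance(mask, BinaryMask):
        data = mask.data
        kind = kind or mask.kind
    else:
        data = np.asarray(mask, dtype=bool)
        kind = kind or "hemorrhage"
    if kind == "motion":
        raise ValueError("motion masks do not yield detections directly")
    labeled = measure.label(data, connectivity=2)
    detections: list[Detection] = []
    for region in measure.regionprops(labeled):
        if region.area < min_area:
            continue
        # fill interior holes so boundary/area describe the entire region,
        # not noise-induced cavities
        sl = region.slice
        comp = np.zeros_like(data)
        comp[sl] = ndimage.binary_fill_holes(labeled[sl] == region.label)
        bnd = boundary_pixels(comp)
        cx, cy = geometric_center(bnd)
        acy, acx = region.centroid  # regionprops returns (row, col)
        detections.append(
            Detection(
                kind=kind,
                centroid=(cx, cy),
                area_px=int(comp.sum()),
                frame_index=frame_index,
                boundary=bnd,
                source=source,
                area_centroid=(float(acx), float(acy)),
            )
        )
    detections.sort(key=lambda d: d.centroid)
    return detections
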