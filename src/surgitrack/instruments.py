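"""Surgical-instrument segmentation: LAB k-means clustering plus interframe
motion subtraction.

Unlike the hemorrhage path, no histogram equalization is applied here: the
metallic gray of instruments is separable from tissue by intensity/chroma
directly, so the pipeline consumes raw frames.  The instrument cluster is
the one with minimal chroma sqrt(A^2 + B^2) (gray is colourless in LAB);
ties go to the brighter (higher L) cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, morphology
from sklearn.cluster import KMeans

from .frame_io import Frame
from .regions import BinaryMask, Detection, mask_to_detections

__all__ = [
    "InstrumentParams",
    "ClusterModel",
    "cluster_lab",
    "select_instrument_cluster",
    "motion_mask",
    "combine_and_label",
    "segment_instruments",
]


@dataclass
class InstrumentParams:
    """Tunable parameters of the instrument segmenter."""

    k: int = 3
    kmeans_seed: int = 0
    subsample: int = 15_000  # pixels used to fit k-means on large frames
    diff_threshold: int = 20  # 8-bit levels for motion subtraction
    motion_gating: bool = True
    motion_combine: str = "gate"  # "gate" (component-level) | "and" | "or"
    motion_dilation: int = 7  # square element edge for the motion mask
    min_motion_fraction: float = 0.05  # component overlap needed in "gate" mode
    closing_radius: int = 2
    min_area: int = 200


@dataclass
class ClusterModel:
    """Fitted k-means model in LAB space.

    centers is (k, 3) in (L, A, B); assignment is an H×W grid of cluster
    indices; every pixel is assigned to its nearest center.
    """

    k: int
    centers: np.ndarray
    assignment: np.ndarray
    inertia: float


class DegenerateClusterError(ValueError):
    """Raised when k exceeds the number of distinct pixel values."""


def cluster_lab(
    frame: Frame, k: int = 3, seed: int = 0, subsample: int = 50_000
) -> ClusterModel:
    """Cluster the frame's pixels in LAB space with seeded k-means.

    Standard Lloyd iterations (k-means++ init, tol 1e-4, max 100 iterations),
    deterministic for a given seed.  Frames larger than ``subsample`` pixels
    are fitted on a seeded random pixel subsample and all pixels are then
    assigned to their nearest center.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    lab = color.rgb2lab(frame.pixels)
    flat = lab.reshape(-1, 3)
    rgb_flat = frame.pixels.reshape(-1, 3)
    # degenerate-input check; the full unique scan runs only when a cheap
    # subsample suggests fewer than k distinct colours
    probe = rgb_flat[:: max(1, rgb_flat.shape[0] // 4096)]
    if len(np.unique(probe, axis=0)) < k:
        n_distinct = len(np.unique(rgb_flat, axis=0))
        if k > n_distinct:
            raise DegenerateClusterError(
                f"k={k} exceeds the {n_distinct} distinct pixel values"
            )
    if flat.shape[0] > subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(flat.shape[0], size=subsample, replace=False)
        fit_data = flat[idx]
    else:
        fit_data = flat
    km = KMeans(n_clusters=k, n_init=1, max_iter=100, tol=1e-4, random_state=seed)
    km.fit(fit_data)
    centers = km.cluster_centers_
    # assign every pixel to its nearest center (squared distance)
    d2 = ((flat[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    assignment = d2.argmin(axis=1).reshape(lab.shape[:2])
    inertia = float(d2.min(axis=1).sum())
    return ClusterModel(k=k, centers=centers, assignment=assignment, inertia=inertia)


def select_instrument_cluster(model: ClusterModel) -> BinaryMask:
    """Mask of the cluster whose center has minimal chroma; ties → higher L."""
    chroma = np.hypot(model.centers[:, 1], model.centers[:, 2])
    L = model.centers[:, 0]
    best = min(range(model.k), key=lambda i: (chroma[i], -L[i]))
    return BinaryMask(model.assignment == best, kind="instrument")


def motion_mask(
    frame_t: Frame, frame_prev: Frame | None, diff_threshold: int = 20
) -> BinaryMask:
    """Interframe motion: max-over-channels absolute difference threshold.

    The first frame of a sequence (``frame_prev is None``) yields an
    all-zero mask.
    """
    if frame_prev is None:
        return BinaryMask(
            np.zeros(frame_t.pixels.shape[:2], dtype=bool), kind="motion"
        )
    if frame_t.pixels.shape != frame_prev.pixels.shape:
        raise ValueError("consecutive frames differ in size")
    diff = np.abs(
        frame_t.pixels.astype(np.int16) - frame_prev.pixels.astype(np.int16)
    ).max(axis=2)
    return BinaryMask(diff > diff_threshold, kind="motion")


def combine_and_label(
    cluster_mask: BinaryMask | np.ndarray,
    motion: BinaryMask | np.ndarray | None,
    params: InstrumentParams | None = None,
    frame_index: int = 0,
) -> list[Detection]:
    """Combine cluster and motion masks and extract instrument candidates.

    With motion gating on, the default "gate" combination keeps each
    cluster component whose overlap with the dilated motion mask is at
    least ``min_motion_fraction`` of its area: motion confirms that a
    candidate moves without carving its shape (a strict pixel-wise "and"
    would shred an instrument translating along its own axis into end-cap
    fragments).  Pixel-wise "and"/"or" combinations are available via
    ``motion_combine``.  A light closing merges fragments before
    components >= ``min_area`` become detections; numbered label
    assignment is deferred to the tracker.
    """
    params = params or InstrumentParams()
    cdata = cluster_mask.data if isinstance(cluster_mask, BinaryMask) else np.asarray(
        cluster_mask, dtype=bool
    )
    mdata = None
    if motion is not None:
        mdata = motion.data if isinstance(motion, BinaryMask) else np.asarray(
            motion, dtype=bool
        )
    if params.motion_gating and mdata is not None:
        dil = ndimage.binary_dilation(
            mdata, structure=np.ones((params.motion_dilation,) * 2, dtype=bool)
        )
        if params.motion_combine == "or":
            combined = cdata | dil
        elif params.motion_combine == "and":
            combined = cdata & dil
        else:  # "gate": keep whole components that overlap the motion mask
            from skimage import measure

            labeled = measure.label(cdata, connectivity=2)
            n = labeled.max()
            if n:
                overlap = np.bincount(labeled[dil].ravel(), minlength=n + 1)
                sizes = np.bincount(labeled.ravel(), minlength=n + 1)
                keep = overlap >= np.maximum(
                    1, params.min_motion_fraction * sizes
                )
                keep[0] = False
                combined = keep[labeled]
            else:
                combined = cdata & False
    else:
        combined = cdata
    if combined.any():
        combined = ndimage.binary_closing(
            combined, structure=morphology.disk(params.closing_radius).astype(bool)
        )
    return mask_to_detections(
        combined, frame_index, kind="instrument", min_area=params.min_area,
        source="segmentation",
    )


def segment_instruments(
    frame: Frame,
    prev_frame: Frame | None,
    params: InstrumentParams | None = None,
) -> list[Detection]:
    """Full per-frame instrument segmentation on raw (unequalized) frames."""
    params = params or InstrumentParams()
    model = cluster_lab(
        frame, k=params.k, seed=params.kmeans_seed, subsample=params.subsample
    )
    cmask = select_instrument_cluster(model)
    mmask = motion_mask(frame, prev_frame, params.diff_threshold)
    return combine_and_label(cmask, mmask, params, frame.index)
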