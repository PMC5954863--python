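"""Evaluation metrics: recall/precision with a centroid-distance TP
criterion, hemorrhage presence accuracy, and centroid RMSE.

A detection is a true positive when its centroid lies within τ = width/15
of a ground-truth centroid (≈ 42.7 px at 640×480); a matched pair beyond τ
counts both a false positive and a false negative; unmatched detections are
false positives and unmatched truths false negatives.  All distances are in
pixels — physical-unit conversion is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .regions import Detection

__all__ = [
    "EvalReport",
    "tp_threshold",
    "match_to_truth",
    "recall_precision",
    "presence_accuracy",
    "rmse",
    "evaluate_sequence",
]

Point = tuple[float, float]


def tp_threshold(image_width: int, image_height: int, mode: str = "width15") -> float:
    """TP centroid-distance threshold τ.

    "width15" (default) is width/15; "height15" and "diag15" variants are
    available for sensitivity checks.
    """
    if mode == "width15":
        return image_width / 15.0
    if mode == "height15":
        return image_height / 15.0
    if mode == "diag15":
        return math.hypot(image_width, image_height) / 15.0
    raise ValueError(f"unknown threshold mode {mode!r}")


@dataclass
class EvalReport:
    """Aggregated detection/tracking performance over a sequence."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    recall: float | None = None
    precision: float | None = None
    presence_accuracy: float | None = None
    rmse_px: float | None = None
    per_frame_errors: list[tuple[int, float]] = field(default_factory=list)
    per_track_rmse: dict[int, float] = field(default_factory=dict)


def _centroid(obj) -> Point:
    return obj.centroid if hasattr(obj, "centroid") else (float(obj[0]), float(obj[1]))


def match_to_truth(
    detections: Sequence,
    truths: Sequence,
    image_width: int = 640,
    image_height: int = 480,
    tau: float | None = None,
) -> tuple[int, int, int, list[tuple[int, int, float]]]:
    """Greedy centroid matching of one frame's detections against truth.

    Accepts Detections, AnnotationRecords, or bare (x, y) pairs.  Returns
    ``(TP, FP, FN, matched_pairs)`` where matched_pairs holds
    ``(detection_index, truth_index, distance)`` for every greedy match
    regardless of τ (used for RMSE pooling).
    """
    if tau is None:
        tau = tp_threshold(image_width, image_height)
    pairs = []
    for di, det in enumerate(detections):
        dx, dy = _centroid(det)
        for ti, tr in enumerate(truths):
            tx, ty = _centroid(tr)
            pairs.append((math.hypot(dx - tx, dy - ty), di, ti))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched: list[tuple[int, int, float]] = []
    tp = fp = 0
    for d, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matched.append((di, ti, d))
        if d < tau:
            tp += 1
        else:
            fp += 1  # matched but too far: false alarm, truth stays missed
    fp += len(detections) - len(used_d)
    fn = len(truths) - tp
    return tp, fp, fn, matched


def recall_precision(
    tp: int, fp: int, fn: int
) -> tuple[float | None, float | None]:
    """Recall = TP/(TP+FN), precision = TP/(TP+FP); None when undefined."""
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    return recall, precision


def presence_accuracy(
    detections_per_frame: Sequence[Sequence],
    truths_per_frame: Sequence[Sequence],
) -> float:
    """Fraction of frames whose binary object-presence matches the truth."""
    n = max(len(detections_per_frame), len(truths_per_frame))
    if n == 0:
        return 1.0
    agree = 0
    for i in range(n):
        has_d = i < len(detections_per_frame) and len(detections_per_frame[i]) > 0
        has_t = i < len(truths_per_frame) and len(truths_per_frame[i]) > 0
        agree += has_d == has_t
    return agree / n


def rmse(estimates: Sequence[Point], references: Sequence[Point]) -> float:
    """Root mean squared Euclidean centroid distance over paired lists."""
    if len(estimates) != len(references):
        raise ValueError("estimate and reference lists differ in length")
    if not estimates:
        raise ValueError("empty input")
    est = np.asarray([_centroid(e) for e in estimates], dtype=float)
    ref = np.asarray([_centroid(r) for r in references], dtype=float)
    return float(np.sqrt(np.mean(np.sum((est - ref) ** 2, axis=1))))


def evaluate_sequence(
    detections_per_frame: Sequence[Sequence],
    truths_per_frame: Sequence[Sequence],
    image_width: int = 640,
    image_height: int = 480,
    tau_mode: str = "width15",
    kind: str | None = None,
) -> EvalReport:
    """Aggregate TP/FP/FN, recall/precision, presence accuracy and pooled
    RMSE over a sequence.

    ``detections_per_frame[i]`` and ``truths_per_frame[i]`` are the frame-i
    objects; ``kind`` optionally restricts both sides to one object class.
    RMSE pools all greedy-matched pairs (no τ cutoff) so that methods that
    mislocalize are penalized rather than silently dropped.
    """
    tau = tp_threshold(image_width, image_height, tau_mode)
    n = max(len(detections_per_frame), len(truths_per_frame))
    report = EvalReport()
    sq_errors: list[float] = []
    track_sq: dict[int, list[float]] = {}
    dets_pf, truths_pf = [], []
    for i in range(n):
        dets = list(detections_per_frame[i]) if i < len(detections_per_frame) else []
        truths = list(truths_per_frame[i]) if i < len(truths_per_frame) else []
        if kind is not None:
            dets = [d for d in dets if getattr(d, "kind", kind) == kind]
            truths = [t for t in truths if getattr(t, "object_kind", kind) == kind]
        dets_pf.append(dets)
        truths_pf.append(truths)
        tp, fp, fn, matched = match_to_truth(dets, truths, image_width, image_height, tau)
        report.tp += tp
        report.fp += fp
        report.fn += fn
        for di, ti, d in matched:
            sq_errors.append(d * d)
            report.per_frame_errors.append((i, d))
            lbl = getattr(dets[di], "label", None)
            if lbl is not None:
                track_sq.setdefault(lbl, []).append(d * d)
    report.recall, report.precision = recall_precision(report.tp, report.fp, report.fn)
    report.presence_accuracy = presence_accuracy(dets_pf, truths_pf)
    if sq_errors:
        report.rmse_px = float(np.sqrt(np.mean(sq_errors)))
    report.per_track_rmse = {
        lbl: float(np.sqrt(np.mean(v))) for lbl, v in sorted(track_sq.items())
    }
    return report
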