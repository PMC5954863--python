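"""Federated multi-object tracking over segmentation + template matching.

Per object the tracker runs two local constant-velocity Kalman filters —
one per measurement source — and an information-weighted master fusion
(see :mod:`surgitrack.kalman`).  On top of the filters it manages:

* numbered labels, assigned once at first detection and never reused;
* greedy nearest-neighbour association of detections to tracks, gated by a
  Euclidean radius;
* per-track lifetimes: continual recognition adds 20 percentage points (cap
  100), a missed frame subtracts the decay (default 20); a track at 0 is
  removed ("does not exist");
* rolling template buffers fed by accepted segmentation detections, so the
  template freezes (rather than absorbing the occluder) while the object is
  hidden;
* coasting: with no accepted measurement the fused output propagates on
  prediction alone, so a temporarily occluded object keeps an estimate.

New tracks spawn from segmentation detections that are unassigned *and* not
within the spawn-suppression radius of a live track of the same kind; the
suppression keeps occlusion-split mask fragments from minting spurious
labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .frame_io import Frame
from .hemorrhage import HemorrhageParams, segment_hemorrhage
from .instruments import InstrumentParams, segment_instruments
from .kalman import (
    KalmanState,
    constant_velocity_state,
    fuse_estimates,
    local_update,
    predict,
)
from .matching import TemplateBuffer, extract_crop, match, update_template
from .regions import Detection

__all__ = [
    "TrackerParams",
    "Track",
    "associate_labels",
    "update_lifetime",
    "FederatedTracker",
    "TrackingResult",
    "track_sequence",
]


@dataclass
class TrackerParams:
    """Filter, gating, lifetime, and template parameters of the tracker."""

    q_pos: float = 1.0
    q_vel: float = 4.0
    r0: float = 9.0
    p0_pos: float = 25.0
    p0_vel: float = 25.0
    gate_radius: float = 64.0
    d_ref: float = 32.0
    # association also requires areas to be consistent: detection area within
    # a factor of the track's last accepted area (0 disables).  Occluders and
    # segmentation clutter rarely match the tracked object's size.
    area_ratio_gate: float = 2.5
    max_coast: int = 10  # frames a local may coast before exclusion from fusion
    lifetime_spawn: float = 20.0
    lifetime_gain: float = 20.0
    # decay per missed frame: slow enough that a track coasts through a
    # multi-second occlusion (the +20 recognition rule is fixed; the decay
    # rate is a free parameter)
    lifetime_decay: float = 4.0
    spawn_suppression_radius: float = 64.0
    hemorrhage_max_tracks: int = 1  # single-region default; 0 = unlimited
    template_window_s: float = 0.5
    search_halfwidth: int = 48
    # a template match counts as a recognition only when its mean per-pixel
    # SSD residual is below this (a minimum always exists somewhere; a bad
    # one means the object is not actually visible)
    tmpl_max_mse: float = 500.0
    # scalar image used for template crops/matching, per object kind:
    # blood is uniquely dark in the green channel (hemoglobin absorption),
    # instruments are uniquely bright in luma
    template_channel_hemorrhage: str = "green"
    template_channel_instrument: str = "luma"
    min_template_dim: int = 8
    max_template_dim: int = 128
    fps: float = 10.0


@dataclass
class Track:
    """A persistent object identity with two local filters and a master."""

    label: int
    kind: str
    local_seg: KalmanState
    local_tmpl: KalmanState
    master_x: np.ndarray
    master_P: np.ndarray
    lifetime: float
    template_buffer: TemplateBuffer | None
    last_seg_frame: int
    last_tmpl_frame: int
    prev_position: tuple[float, float]
    last_area: int
    spawn_frame: int

    @property
    def position(self) -> tuple[float, float]:
        return float(self.master_x[0]), float(self.master_x[1])

    def predicted_position(self) -> tuple[float, float]:
        return (
            float(self.master_x[0] + self.master_x[2]),
            float(self.master_x[1] + self.master_x[3]),
        )


def update_lifetime(
    track: Track, was_recognized: bool, gain: float = 20.0, decay: float = 20.0
) -> Track:
    """Apply the lifetime rule: +gain on recognition (cap 100), −decay on a
    miss (floor 0).  The caller removes the track when lifetime hits 0."""
    if was_recognized:
        track.lifetime = min(100.0, track.lifetime + gain)
    else:
        track.lifetime = max(0.0, track.lifetime - decay)
    return track


def associate_labels(
    tracks: Sequence[Track],
    detections: Sequence[Detection],
    gate_radius: float = 64.0,
    area_ratio_gate: float = 0.0,
) -> tuple[dict[int, int], list[int]]:
    """Greedy nearest-neighbour assignment of detections to tracks.

    Pairs are taken in ascending Euclidean distance between the detection
    centroid and the track's predicted position (ties broken by track
    label, then detection x, then y); each side is used at most once and
    pairs beyond ``gate_radius`` stay unassigned.  With ``area_ratio_gate``
    set, a pair is also skipped when the detection's area differs from the
    track's last accepted area by more than that factor.  Returns
    ``(track_index -> detection_index, unassigned detection indices)``.
    """
    pairs = []
    for ti, tr in enumerate(tracks):
        px, py = tr.predicted_position()
        for di, det in enumerate(detections):
            d = math.hypot(det.centroid[0] - px, det.centroid[1] - py)
            if d > gate_radius:
                continue
            if area_ratio_gate and tr.last_area > 0 and det.area_px > 0:
                ratio = max(det.area_px / tr.last_area, tr.last_area / det.area_px)
                if ratio > area_ratio_gate:
                    continue
            pairs.append((d, tr.label, det.centroid[0], det.centroid[1], ti, di))
    pairs.sort()
    assigned: dict[int, int] = {}
    used_dets: set[int] = set()
    for d, _, _, _, ti, di in pairs:
        if ti in assigned or di in used_dets:
            continue
        assigned[ti] = di
        used_dets.add(di)
    unassigned = [di for di in range(len(detections)) if di not in used_dets]
    return assigned, unassigned


def _luma(pixels: np.ndarray) -> np.ndarray:
    w = np.array([0.299, 0.587, 0.114])
    return pixels.astype(float) @ w


def _scalar_image(pixels: np.ndarray, channel: str) -> np.ndarray:
    """Scalar image used for template matching ("luma" | "green")."""
    if channel == "green":
        return pixels[..., 1].astype(float)
    return _luma(pixels)


class FederatedTracker:
    """Tracks objects of one kind across a frame sequence."""

    def __init__(self, kind: str, params: TrackerParams | None = None,
                 first_label: int = 1, max_tracks: int = 0):
        self.kind = kind
        self.params = params or TrackerParams()
        self.tracks: list[Track] = []
        self.max_tracks = max_tracks  # 0 = unlimited
        self._next_label = first_label
        self.history: list[dict] = []

    # -- internals ---------------------------------------------------------

    def _new_state(self, x: float, y: float) -> KalmanState:
        p = self.params
        return constant_velocity_state(
            x, y, q_pos=p.q_pos, q_vel=p.q_vel, r0=p.r0,
            p0_pos=p.p0_pos, p0_vel=p.p0_vel,
        )

    def _spawn(self, det: Detection, gray: np.ndarray, frame_index: int) -> Track:
        p = self.params
        x, y = det.centroid
        state = self._new_state(x, y)
        buffer = None
        if det.boundary is not None and det.boundary.size:
            bw = float(det.boundary[:, 0].max() - det.boundary[:, 0].min()) + 1
            bh = float(det.boundary[:, 1].max() - det.boundary[:, 1].min()) + 1
            h = int(np.clip(round(bh), p.min_template_dim, p.max_template_dim))
            w = int(np.clip(round(bw), p.min_template_dim, p.max_template_dim))
            buffer = TemplateBuffer(
                shape=(h, w), window_s=p.template_window_s, fps=p.fps
            )
            update_template(buffer, extract_crop(gray, det.centroid, (h, w)))
        track = Track(
            label=self._next_label,
            kind=self.kind,
            local_seg=state,
            local_tmpl=self._new_state(x, y),
            master_x=state.x.copy(),
            master_P=state.P.copy(),
            lifetime=p.lifetime_spawn,
            template_buffer=buffer,
            last_seg_frame=frame_index,
            last_tmpl_frame=frame_index,
            prev_position=(x, y),
            last_area=det.area_px,
            spawn_frame=frame_index,
        )
        self._next_label += 1
        self.tracks.append(track)
        return track

    # -- one frame ---------------------------------------------------------

    def step(
        self, frame: Frame, seg_detections: Sequence[Detection]
    ) -> list[Detection]:
        """Advance all tracks by one frame; returns the fused detections."""
        p = self.params
        i = frame.index
        channel = (p.template_channel_hemorrhage if self.kind == "hemorrhage"
                   else p.template_channel_instrument)
        gray = _scalar_image(frame.pixels, channel)

        # template measurements around each track's predicted position
        tmpl_meas: dict[int, tuple[float, float]] = {}
        for ti, tr in enumerate(self.tracks):
            if tr.template_buffer is None or tr.template_buffer.template is None:
                continue
            det = match(
                gray,
                tr.template_buffer,
                search_center=tr.predicted_position(),
                search_halfwidth=p.search_halfwidth,
                prev_position=tr.prev_position,
                frame_index=i,
                kind=self.kind,
            )
            if det is not None and det.score is not None and det.score <= p.tmpl_max_mse:
                tmpl_meas[ti] = det.centroid

        assigned, unassigned = associate_labels(
            self.tracks, seg_detections, p.gate_radius, p.area_ratio_gate
        )

        fused_out: list[Detection] = []
        survivors: list[Track] = []
        for ti, tr in enumerate(self.tracks):
            seg_det = seg_detections[assigned[ti]] if ti in assigned else None
            # appearance verification: an associable region that does not
            # resemble the track's template is clutter, not the object
            if (
                seg_det is not None
                and tr.template_buffer is not None
                and tr.template_buffer.template is not None
            ):
                crop = extract_crop(gray, seg_det.centroid, tr.template_buffer.shape)
                resid = float(np.mean((crop - tr.template_buffer.template) ** 2))
                if resid > p.tmpl_max_mse:
                    seg_det = None
            seg_z = seg_det.centroid if seg_det is not None else None
            tr.local_seg, seg_ok = local_update(
                tr.local_seg, seg_z, p.gate_radius, tr.prev_position, p.d_ref
            )
            tr.local_tmpl, tmpl_ok = local_update(
                tr.local_tmpl, tmpl_meas.get(ti), p.gate_radius,
                tr.prev_position, p.d_ref,
            )
            if seg_ok:
                tr.last_seg_frame = i
                tr.last_area = seg_det.area_px
            if tmpl_ok:
                tr.last_tmpl_frame = i

            estimates = []
            if i - tr.last_seg_frame <= p.max_coast:
                estimates.append((tr.local_seg.x, tr.local_seg.P))
            if (
                tr.template_buffer is not None
                and len(tr.template_buffer.crops) > 0
                and i - tr.last_tmpl_frame <= p.max_coast
            ):
                estimates.append((tr.local_tmpl.x, tr.local_tmpl.P))
            if estimates:
                tr.master_x, tr.master_P = fuse_estimates(estimates)
            else:  # both locals stale: coast the master on prediction alone
                F = tr.local_seg.F
                Q = tr.local_seg.Q
                tr.master_x = F @ tr.master_x
                tr.master_P = F @ tr.master_P @ F.T + Q

            recognized = seg_ok or tmpl_ok
            update_lifetime(tr, recognized, p.lifetime_gain, p.lifetime_decay)
            self.history.append(
                {
                    "frame": i,
                    "label": tr.label,
                    "kind": tr.kind,
                    "x": float(tr.master_x[0]),
                    "y": float(tr.master_x[1]),
                    "lifetime": tr.lifetime,
                    "seg": bool(seg_ok),
                    "template": bool(tmpl_ok),
                }
            )
            if tr.lifetime <= 0.0:
                continue  # track removed

            # template crops come from accepted segmentation detections only,
            # so occluders never contaminate the template
            if seg_ok and tr.template_buffer is not None:
                update_template(
                    tr.template_buffer,
                    extract_crop(gray, seg_det.centroid, tr.template_buffer.shape),
                )
            tr.prev_position = (float(tr.master_x[0]), float(tr.master_x[1]))
            fused_out.append(
                Detection(
                    kind=self.kind,
                    centroid=tr.prev_position,
                    area_px=tr.last_area,
                    frame_index=i,
                    source="fused",
                    label=tr.label,
                )
            )
            survivors.append(tr)
        self.tracks = survivors

        # spawn new tracks from unassigned detections away from live tracks
        for di in unassigned:
            if self.max_tracks and len(self.tracks) >= self.max_tracks:
                break
            det = seg_detections[di]
            near_existing = any(
                math.hypot(det.centroid[0] - tr.position[0],
                           det.centroid[1] - tr.position[1])
                <= p.spawn_suppression_radius
                for tr in self.tracks
            )
            if near_existing:
                continue
            tr = self._spawn(det, gray, i)
            self.history.append(
                {
                    "frame": i,
                    "label": tr.label,
                    "kind": tr.kind,
                    "x": float(tr.master_x[0]),
                    "y": float(tr.master_x[1]),
                    "lifetime": tr.lifetime,
                    "seg": True,
                    "template": False,
                }
            )
            fused_out.append(
                Detection(
                    kind=self.kind,
                    centroid=det.centroid,
                    area_px=det.area_px,
                    frame_index=i,
                    source="fused",
                    label=tr.label,
                )
            )
        fused_out.sort(key=lambda d: d.label or 0)
        return fused_out


@dataclass
class TrackingResult:
    """Output of a tracking run over a frame sequence."""

    fused: list[list[Detection]]  # per frame, all kinds merged
    segmentation: list[list[Detection]]  # raw per-frame segmentation output
    history: list[dict]


def track_sequence(
    frames: Sequence[Frame],
    tracker_params: TrackerParams | None = None,
    hemorrhage_params: HemorrhageParams | None = None,
    instrument_params: InstrumentParams | None = None,
    kinds: Sequence[str] = ("hemorrhage", "instrument"),
) -> TrackingResult:
    """Run segmentation → template matching → federated fusion over frames.

    ``kinds`` selects which object classes to process.  The per-frame fused
    output contains one Detection per live track; during total occlusion it
    coasts on prediction, so a track that stays alive yields an estimate in
    every frame.
    """
    tp = tracker_params or TrackerParams()
    hp = hemorrhage_params or HemorrhageParams()
    ip = instrument_params or InstrumentParams()
    trackers: dict[str, FederatedTracker] = {}
    if "hemorrhage" in kinds:
        trackers["hemorrhage"] = FederatedTracker(
            "hemorrhage", tp, first_label=0, max_tracks=tp.hemorrhage_max_tracks
        )
    if "instrument" in kinds:
        trackers["instrument"] = FederatedTracker("instrument", tp, first_label=1)

    fused_all: list[list[Detection]] = []
    seg_all: list[list[Detection]] = []
    prev: Frame | None = None
    for frame in frames:
        seg_frame: list[Detection] = []
        fused_frame: list[Detection] = []
        if "hemorrhage" in trackers:
            dets = segment_hemorrhage(frame, hp)
            seg_frame.extend(dets)
            fused_frame.extend(trackers["hemorrhage"].step(frame, dets))
        if "instrument" in trackers:
            dets = segment_instruments(frame, prev, ip)
            seg_frame.extend(dets)
            fused_frame.extend(trackers["instrument"].step(frame, dets))
        seg_all.append(seg_frame)
        fused_all.append(fused_frame)
        prev = frame

    history = []
    for tk in trackers.values():
        history.extend(tk.history)
    history.sort(key=lambda h: (h["frame"], h["kind"], h["label"]))
    return TrackingResult(fused=fused_all, segmentation=seg_all, history=history)
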