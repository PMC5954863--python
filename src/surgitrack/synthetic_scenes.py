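"""Synthetic laparoscopic scene generator with exact ground truth.

Renders surgery-like frame sequences: a textured reddish tissue background
with drifting illumination, specular speckle and per-pixel sensor noise;
dark-red blood blobs whose area follows a scripted profile; gray elongated
instruments on known trajectories; and scripted occlusion events (opaque
tissue-coloured or blood-smeared patches, semi-transparent smoke).

Ground truth persists through occlusions: the annotation of an object is
derived from its rendered mask *before* noise and occluders are applied, so
tracker robustness during occlusion is measurable against exact truth.

All randomness comes from a single seeded generator per scene; rendering is
bit-deterministic for a given spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw

from .frame_io import AnnotationRecord, Frame
from .regions import boundary_pixels, geometric_center

__all__ = [
    "SceneSpecError",
    "BloodEvent",
    "InstrumentSpec",
    "OcclusionEvent",
    "SceneSpec",
    "linear_path",
    "render_scene",
    "preset_hemorrhage_occlusion",
    "preset_three_instruments",
    "preset_stagnant_bleed",
    "preset_acute_bleed",
    "PRESETS",
]


class SceneSpecError(ValueError):
    """Raised when a scene spec is inconsistent (e.g. object spawns off-frame)."""


PathFn = Callable[[int], tuple[float, float]]


def linear_path(
    start: tuple[float, float],
    velocity: tuple[float, float],
    sine_amp: tuple[float, float] = (0.0, 0.0),
    sine_period: float = 60.0,
    phase: float = 0.0,
) -> PathFn:
    """Constant-velocity trajectory with an optional sinusoidal component."""

    def path(i: int) -> tuple[float, float]:
        s = math.sin(2.0 * math.pi * i / sine_period + phase)
        return (
            start[0] + velocity[0] * i + sine_amp[0] * s,
            start[1] + velocity[1] * i + sine_amp[1] * s,
        )

    return path


@dataclass
class BloodEvent:
    """A blood blob: centroid path and a per-frame area profile (px^2)."""

    path: PathFn
    area: Callable[[int], float]
    start_frame: int = 0
    end_frame: int | None = None
    color: tuple[int, int, int] = (150, 20, 25)

    def active(self, i: int, n_frames: int) -> bool:
        end = n_frames if self.end_frame is None else self.end_frame
        return self.start_frame <= i < end


@dataclass
class InstrumentSpec:
    """An elongated gray instrument: rotated rectangle on a known trajectory."""

    label: int
    path: PathFn
    length: float = 120.0
    width: float = 24.0
    angle_deg: float | Callable[[int], float] = 0.0
    color: tuple[int, int, int] = (170, 170, 175)

    def angle_at(self, i: int) -> float:
        a = self.angle_deg
        return float(a(i)) if callable(a) else float(a)


@dataclass
class OcclusionEvent:
    """A scripted occluder active over [start_frame, end_frame] inclusive.

    mode "opaque" paints a coloured patch over everything already drawn;
    mode "smoke" alpha-blends a near-white overlay.
    """

    start_frame: int
    end_frame: int
    center: tuple[float, float] | PathFn
    size: tuple[float, float] = (120.0, 120.0)  # (width, height) px
    color: tuple[int, int, int] = (120, 70, 65)
    mode: str = "opaque"
    alpha: float = 0.55  # smoke opacity

    def active(self, i: int) -> bool:
        return self.start_frame <= i <= self.end_frame

    def center_at(self, i: int) -> tuple[float, float]:
        c = self.center
        return c(i) if callable(c) else c


@dataclass
class SceneSpec:
    """Full description of a synthetic scene."""

    width: int = 640
    height: int = 480
    n_frames: int = 200
    fps: float = 10.0
    seed: int = 0
    background_rgb: tuple[int, int, int] = (105, 70, 68)
    texture_amp: float = 0.12  # multiplicative low-frequency texture
    texture_cells: tuple[int, int] = (12, 16)  # (rows, cols) of the noise grid
    illumination: Callable[[int], float] | None = None  # per-frame gain
    specular_rate: float = 4e-5  # specular discs per pixel per frame
    sensor_noise_sigma: float = 3.0  # per-pixel Gaussian noise, 8-bit levels
    blood_events: list[BloodEvent] = field(default_factory=list)
    instruments: list[InstrumentSpec] = field(default_factory=list)
    occlusions: list[OcclusionEvent] = field(default_factory=list)

    def gain(self, i: int) -> float:
        if self.illumination is None:
            return 1.0 + 0.03 * math.sin(2.0 * math.pi * i / 120.0)
        return float(self.illumination(i))


def _blob_mask(spec: SceneSpec, ev: BloodEvent, i: int) -> np.ndarray:
    x, y = ev.path(i)
    r = math.sqrt(max(ev.area(i), 0.0) / math.pi)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    if r <= 0:
        return mask
    rr, cc = skdraw.disk((y, x), r, shape=mask.shape)
    mask[rr, cc] = True
    return mask


def _instrument_mask(spec: SceneSpec, ins: InstrumentSpec, i: int) -> np.ndarray:
    cx, cy = ins.path(i)
    th = math.radians(ins.angle_at(i))
    ux, uy = math.cos(th), math.sin(th)  # along length
    vx, vy = -math.sin(th), math.cos(th)  # along width
    hl, hw = ins.length / 2.0, ins.width / 2.0
    corners = [
        (cx + s1 * hl * ux + s2 * hw * vx, cy + s1 * hl * uy + s2 * hw * vy)
        for s1, s2 in ((-1, -1), (-1, 1), (1, 1), (1, -1))
    ]
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    rr, cc = skdraw.polygon(
        [c[1] for c in corners], [c[0] for c in corners], shape=mask.shape
    )
    mask[rr, cc] = True
    return mask


def _annotate(mask: np.ndarray, kind: str, label: int, i: int) -> AnnotationRecord | None:
    if not mask.any():
        return None
    bnd = boundary_pixels(mask)
    cx, cy = geometric_center(bnd)
    return AnnotationRecord(
        frame_index=i,
        object_kind=kind,
        object_label=label,
        centroid=(cx, cy),
        boundary=[(float(x), float(y)) for x, y in bnd],
        area_px=int(mask.sum()),
    )


def render_scene(spec: SceneSpec) -> tuple[list[Frame], list[AnnotationRecord]]:
    """Render a scene spec into frames plus exact per-frame annotations.

    Raises :class:`SceneSpecError` if an object is fully outside the frame
    at its spawn frame.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width

    # static low-frequency multiplicative texture field
    cy, cx = spec.texture_cells
    grid = rng.normal(size=(cy, cx))
    field_ = ndimage.zoom(grid, (H / cy, W / cx), order=3)[:H, :W]
    peak = float(np.abs(field_).max()) or 1.0
    texture = 1.0 + spec.texture_amp * (field_ / peak)

    frames: list[Frame] = []
    annotations: list[AnnotationRecord] = []

    for i in range(spec.n_frames):
        img = np.empty((H, W, 3), dtype=np.float32)
        img[:] = np.asarray(spec.background_rgb, dtype=np.float32)

        for ev in spec.blood_events:
            if not ev.active(i, spec.n_frames):
                continue
            mask = _blob_mask(spec, ev, i)
            if i == ev.start_frame and ev.area(i) > 0 and not mask.any():
                raise SceneSpecError(f"blood event spawns fully outside frame at {i}")
            rec = _annotate(mask, "hemorrhage", 0, i)
            if rec is not None:
                annotations.append(rec)
            img[mask] = np.asarray(ev.color, dtype=np.float32)

        for ins in spec.instruments:
            mask = _instrument_mask(spec, ins, i)
            if i == 0 and not mask.any():
                raise SceneSpecError(
                    f"instrument {ins.label} spawns fully outside frame"
                )
            rec = _annotate(mask, "instrument", ins.label, i)
            if rec is not None:
                annotations.append(rec)
            img[mask] = np.asarray(ins.color, dtype=np.float32)

        for occ in spec.occlusions:
            if not occ.active(i):
                continue
            ox, oy = occ.center_at(i)
            hw, hh = occ.size[0] / 2.0, occ.size[1] / 2.0
            r0, r1 = max(0, int(round(oy - hh))), min(H, int(round(oy + hh)))
            c0, c1 = max(0, int(round(ox - hw))), min(W, int(round(ox + hw)))
            if r1 <= r0 or c1 <= c0:
                continue
            col = np.asarray(occ.color, dtype=np.float32)
            if occ.mode == "smoke":
                patch = img[r0:r1, c0:c1]
                img[r0:r1, c0:c1] = (1 - occ.alpha) * patch + occ.alpha * np.asarray(
                    (245.0, 245.0, 245.0), dtype=np.float32
                )
            else:
                img[r0:r1, c0:c1] = col

        # multiplicative texture and illumination drift over the whole scene
        img *= (texture * spec.gain(i))[..., None]

        # specular speckle: small near-white discs
        n_spec = rng.poisson(spec.specular_rate * H * W)
        for _ in range(n_spec):
            sy = rng.uniform(0, H)
            sx = rng.uniform(0, W)
            sr = rng.uniform(1.0, 3.0)
            val = rng.uniform(235.0, 255.0)
            rr, cc = skdraw.disk((sy, sx), sr, shape=(H, W))
            img[rr, cc] = val

        if spec.sensor_noise_sigma > 0:
            img += rng.normal(0.0, spec.sensor_noise_sigma, size=img.shape).astype(
                np.float32
            )

        pixels = np.clip(img, 0, 255).astype(np.uint8)
        frames.append(Frame(index=i, time_s=i / spec.fps, pixels=pixels))

    return frames, annotations


# ---------------------------------------------------------------------------
# Presets mirroring the study conditions
# ---------------------------------------------------------------------------


def preset_hemorrhage_occlusion(seed: int = 7) -> SceneSpec:
    """One moving blood blob, fully hidden by a blood-smeared tissue patch
    for frames 100–120.

    The occluder is reddish enough that colour segmentation falsely locks
    onto it ~95 px away from the true (hidden) blob centre, emulating a
    false segmentation during occlusion; the truth annotation persists.
    """
    path = linear_path((200.0, 240.0), (1.2, 0.3))

    def occ_center(i: int) -> tuple[float, float]:
        x, y = path(i)
        return (x + 95.0, y)

    return SceneSpec(
        n_frames=200,
        seed=seed,
        blood_events=[BloodEvent(path=path, area=lambda i: 2000.0)],
        occlusions=[
            OcclusionEvent(
                start_frame=100,
                end_frame=120,
                center=occ_center,
                size=(270.0, 270.0),
                color=(170, 60, 60),  # blood-smeared tissue: triggers the segmenter
                mode="opaque",
            )
        ],
    )


def preset_three_instruments(seed: int = 11) -> SceneSpec:
    """Three instruments on distinct constant-velocity + sinusoidal paths.

    Instruments 1 and 2 pass close to each other around frame 100; a
    tissue-coloured patch briefly hides instrument 3 (frames 120–127).
    """
    i1 = InstrumentSpec(
        label=1,
        path=linear_path((100.0, 120.0), (1.5, 0.45), sine_amp=(0.0, 12.0), sine_period=60.0),
        angle_deg=15.0,
        color=(168, 168, 172),
    )
    i2 = InstrumentSpec(
        label=2,
        path=linear_path((540.0, 420.0), (-1.3, -0.75), sine_amp=(8.0, 0.0), sine_period=80.0),
        angle_deg=170.0,
        color=(175, 175, 180),
    )
    i3 = InstrumentSpec(
        label=3,
        path=linear_path((90.0, 300.0), (0.9, 0.35)),
        angle_deg=60.0,
        color=(182, 182, 186),
    )
    occ_xy = i3.path(123)
    return SceneSpec(
        n_frames=200,
        seed=seed,
        instruments=[i1, i2, i3],
        occlusions=[
            OcclusionEvent(
                start_frame=120,
                end_frame=127,
                center=occ_xy,
                size=(170.0, 170.0),
                color=(120, 70, 65),  # matches tissue: instrument simply vanishes
                mode="opaque",
            )
        ],
    )


def _stagnant_area(i: int) -> float:
    # near-constant area with a transient dip (smoke/occlusion artefact window)
    base = 2000.0
    if i < 40:
        return base
    if i < 52:
        return base - 120.0 * (i - 40) / 12.0
    if i < 68:
        return base - 120.0
    if i < 93:
        return base - 120.0 + 120.0 * (i - 68) / 25.0
    return base


def preset_stagnant_bleed(seed: int = 13) -> SceneSpec:
    """Near-constant blood area with a transient dip around frames 40–80,
    plus a semi-transparent smoke patch grazing the blob edge."""
    path = linear_path((320.0, 240.0), (0.05, 0.02))
    return SceneSpec(
        n_frames=200,
        seed=seed,
        blood_events=[BloodEvent(path=path, area=_stagnant_area)],
        occlusions=[
            OcclusionEvent(
                start_frame=45,
                end_frame=75,
                center=(368.0, 278.0),
                size=(60.0, 60.0),
                mode="smoke",
            )
        ],
    )


def _acute_area(i: int) -> float:
    if i <= 50:
        return 300.0 + 74.0 * i  # rapid flow: ~4000 px^2 by frame 50
    if i <= 60:
        return 4000.0
    return max(4000.0 - 26.0 * (i - 60), 300.0)  # linear decrease after stanch


def preset_acute_bleed(seed: int = 17) -> SceneSpec:
    """Acute bleed: area rising rapidly for the first 50 frames, then a
    plateau and a linear decrease once the bleed is stanched."""
    path = linear_path((300.0, 220.0), (0.1, 0.05))
    return SceneSpec(
        n_frames=200,
        seed=seed,
        blood_events=[BloodEvent(path=path, area=_acute_area)],
    )


PRESETS: dict[str, Callable[..., SceneSpec]] = {
    "hemorrhage_occlusion": preset_hemorrhage_occlusion,
    "three_instruments": preset_three_instruments,
    "stagnant_bleed": preset_stagnant_bleed,
    "acute_bleed": preset_acute_bleed,
}
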