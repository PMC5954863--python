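"""Shared fixtures: rendered preset scenes and full tracking runs.

Rendering and tracking the 200-frame presets is the expensive part of the
suite, so each is done once per session and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

from surgitrack.metrics import evaluate_sequence
from surgitrack.pipeline import truths_by_frame
from surgitrack.synthetic_scenes import (
    preset_acute_bleed,
    preset_hemorrhage_occlusion,
    preset_stagnant_bleed,
    preset_three_instruments,
    render_scene,
)
from surgitrack.tracking import track_sequence


@pytest.fixture(scope="session")
def scene_hemorrhage_occlusion():
    spec = preset_hemorrhage_occlusion()
    frames, ann = render_scene(spec)
    return spec, frames, ann


@pytest.fixture(scope="session")
def scene_three_instruments():
    spec = preset_three_instruments()
    frames, ann = render_scene(spec)
    return spec, frames, ann


@pytest.fixture(scope="session")
def scene_stagnant_bleed():
    spec = preset_stagnant_bleed()
    frames, ann = render_scene(spec)
    return spec, frames, ann


@pytest.fixture(scope="session")
def scene_acute_bleed():
    spec = preset_acute_bleed()
    frames, ann = render_scene(spec)
    return spec, frames, ann


@pytest.fixture(scope="session")
def run_hemorrhage_occlusion(scene_hemorrhage_occlusion):
    spec, frames, ann = scene_hemorrhage_occlusion
    result = track_sequence(frames, kinds=("hemorrhage",))
    return spec, frames, ann, result


@pytest.fixture(scope="session")
def run_three_instruments(scene_three_instruments):
    spec, frames, ann = scene_three_instruments
    result = track_sequence(frames, kinds=("instrument",))
    return spec, frames, ann, result


@pytest.fixture(scope="session")
def run_stagnant_bleed(scene_stagnant_bleed):
    spec, frames, ann = scene_stagnant_bleed
    result = track_sequence(frames, kinds=("hemorrhage",))
    return spec, frames, ann, result


@pytest.fixture(scope="session")
def run_acute_bleed(scene_acute_bleed):
    spec, frames, ann = scene_acute_bleed
    result = track_sequence(frames, kinds=("hemorrhage",))
    return spec, frames, ann, result


def eval_run(frames, ann, per_frame, kind):
    """Evaluate a per-frame detection list against scene truth."""
    truths = truths_by_frame(ann, len(frames))
    return evaluate_sequence(
        per_frame, truths, image_width=frames[0].width,
        image_height=frames[0].height, kind=kind,
    )
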