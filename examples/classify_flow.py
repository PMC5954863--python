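"""Classify hemorrhage flow from the blood-area time series.

Runs the tracker on the stagnant-bleed and acute-bleed scenes, builds the
per-frame area series with its peak-trend line, and classifies sliding
3-second windows as flowing (warning) or stagnant.
"""

from surgitrack.flow import area_series, classify_flow
from surgitrack.synthetic_scenes import (
    preset_acute_bleed,
    preset_stagnant_bleed,
    render_scene,
)
from surgitrack.tracking import track_sequence

for name, preset in (("stagnant bleed", preset_stagnant_bleed),
                     ("acute bleed", preset_acute_bleed)):
    frames, _ = render_scene(preset())
    result = track_sequence(frames, kinds=("hemorrhage",))
    series = classify_flow(area_series(result.fused))
    n_flow = sum(w.label == "flowing" for w in series.windows)
    n_warn = sum(w.warning for w in series.windows)
    first_warn = next((w.start for w in series.windows if w.warning), None)
    last_warn = next((w.start for w in reversed(series.windows) if w.warning), None)
    print(f"{name}: {len(series.windows)} windows, "
          f"{n_flow} flowing, {n_warn} warnings"
          + (f" (frames {first_warn}..{last_warn})" if n_warn else ""))
# A near-constant area (slope below 10 px^2/frame) is stagnant: no warning.
# The acute bleed raises warnings during its rapid growth phase and goes
# quiet once the area declines after the stanch.
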