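"""Track three surgical instruments and score detection quality.

Renders the three-instrument scene (sinusoidal trajectories, a brief
occlusion of instrument 3), tracks with numbered labels, and reports the
recall/precision at the width/15 centroid criterion plus per-track RMSE.
"""

from collections import Counter

from surgitrack.metrics import evaluate_sequence
from surgitrack.pipeline import truths_by_frame
from surgitrack.synthetic_scenes import preset_three_instruments, render_scene
from surgitrack.tracking import track_sequence

frames, truth = render_scene(preset_three_instruments())
result = track_sequence(frames, kinds=("instrument",))

report = evaluate_sequence(
    result.fused, truths_by_frame(truth, len(frames)), 640, 480, kind="instrument"
)
counts = Counter(h["label"] for h in result.history)

print(f"recall    : {100 * report.recall:5.1f} %   (TP={report.tp}, FN={report.fn})")
print(f"precision : {100 * report.precision:5.1f} %   (FP={report.fp})")
print(f"pooled RMSE: {report.rmse_px:5.2f} px  (TP criterion tau = {640 / 15:.1f} px)")
for label, r in report.per_track_rmse.items():
    print(f"  instrument {label}: RMSE {r:5.2f} px over {counts[label]} frames")
# Each instrument keeps one numbered label for the whole run; the brief
# patch occlusion of instrument 3 is bridged by template matching + coasting.
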