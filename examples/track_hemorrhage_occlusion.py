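"""Track a bleeding region through a 2-second occlusion.

Renders the bundled occlusion scene (a moving blood blob hidden by a
blood-smeared tissue patch for frames 100-120), runs segmentation-only and
the full federated-Kalman tracker, and compares their centroid RMSE
against the exact ground truth.
"""

from surgitrack.metrics import evaluate_sequence
from surgitrack.pipeline import truths_by_frame
from surgitrack.synthetic_scenes import preset_hemorrhage_occlusion, render_scene
from surgitrack.tracking import track_sequence

frames, truth = render_scene(preset_hemorrhage_occlusion())
result = track_sequence(frames, kinds=("hemorrhage",))

truths = truths_by_frame(truth, len(frames))
fused = evaluate_sequence(result.fused, truths, 640, 480, kind="hemorrhage")
seg_only = evaluate_sequence(result.segmentation, truths, 640, 480, kind="hemorrhage")

coverage = 100.0 * sum(1 for d in result.fused if d) / len(frames)
print(f"segmentation-only RMSE : {seg_only.rmse_px:6.2f} px")
print(f"fused tracker RMSE     : {fused.rmse_px:6.2f} px")
print(f"fused frame coverage   : {coverage:6.1f} %")
print(f"presence accuracy      : {100 * fused.presence_accuracy:6.1f} %")
# The segmentation-only output locks onto the occluding patch (~95 px off)
# during frames 100-120; the tracker rejects those measurements and coasts
# on its velocity estimate, so its error stays at the sub-pixel level.
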