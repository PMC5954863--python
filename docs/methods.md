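# Methods

`surgitrack` implements a common detection-and-tracking architecture for
laparoscopic surgery video that handles both a deformable object class
(hemorrhage regions) and rigid ones (surgical instruments) with the same
three-phase structure:

1. **per-frame segmentation** from colour/texture features,
2. **template matching** against a rolling appearance model, and
3. **federated Kalman filtering** that fuses the two measurement streams
   per tracked object.

This note records the model assumptions, the parameters that matter, the
numerical choices, and what the synthetic test scenes do and do not show.

## Coordinate and data conventions

Images are 8-bit RGB, `(height, width, 3)`. Pixel coordinates are 0-based
with origin at the top-left pixel centre, `x` rightward (columns), `y`
downward (rows); every centroid in the package is an `(x, y)` pair. Frame
time is `index / fps`; the reference material is 640×480 at 10 frames/s,
both configurable. A detection's *geometric centre* is the per-axis median
of its boundary pixels (the convention used for the ground truth this kind
of system is scored against); the area centroid is kept alongside for
reference. Region area is the pixel count of the entire (hole-filled)
region. Interior holes are filled before the boundary is measured because
noise-driven cavities otherwise contribute inner-boundary pixels that can
shift the boundary median by several pixels.

## Hemorrhage segmentation

Per frame: histogram equalization independently in R, G and B (contrast
normalisation against illumination drift), then a *mutually inclusive
threshold* — a pixel is blood only if it passes a band threshold in every
channel (defaults on the equalized frame: R ∈ [140, 255], G ∈ [0, 100],
B ∈ [0, 100]). The refinement stage then:

* opens the mask with a 3×3 disc (`opening_radius = 1`). Equalization is
  rank-based, so per-pixel sensor noise decorrelates channel ranks and a
  fraction of background pixels passes the AND by chance; these are almost
  always isolated pixels, which the opening removes before the closing
  step can weld them into blob-sized clusters.
* removes mask pixels whose local grayscale entropy (9×9 window) is below
  `entropy_min = 3.0` bits. Flat saturated regions — specular highlights —
  carry near-zero local entropy; any region showing real texture or sensor
  noise carries well over 3 bits. On a perfectly noiseless synthetic image
  every flat region fails this test, so for such degenerate inputs the
  filter should be disabled (`entropy_min = 0`).
* closes contour gaps: canny edges (σ = 1.0) adjacent to the mask are
  merged in and a 5×5 disc closing is applied, constrained so the result
  never extends beyond the input mask's dilation by the closing element.
* drops components below `min_area = 150` px (≈ 7 px radius). Smaller
  candidates at 640×480 are indistinguishable from threshold noise.

Connected components (8-connectivity) of the refined mask become
detections.

## Instrument segmentation

No histogram equalization here — metallic gray separates from tissue by
intensity and chroma directly. The frame is converted to LAB (sRGB/D65)
and clustered with seeded k-means (`k = 3`: instrument / tissue / dark
background; k-means++ init, tol 1e-4, ≤ 100 Lloyd iterations). Frames
above 15 000 pixels are fitted on a seeded random subsample and all pixels
assigned to the nearest centre; with `k = 3` well-separated material
classes this is equivalent to the full fit at a fraction of the cost. The
instrument cluster is the one with minimal chroma √(A²+B²) (gray is
colourless), ties to the brighter cluster.

Interframe motion (max-over-channels absolute difference > 20 levels)
gates the cluster mask at the *component* level: a cluster component is
kept if at least 5 % of its area overlaps the 7×7-dilated motion mask.
Component-level gating was chosen over a pixel-wise AND because a rigid
instrument translating along its own axis produces motion only at its end
caps — the pixel AND shreds it into fragments, while component gating
keeps the full shape and still rejects static gray distractors (whose
motion overlap is only the ~0.25 % noise floor). Pixel-wise `and`/`or`
remain available through `motion_combine`. Components ≥ 200 px become
instrument candidates; numbered labels are the tracker's job.

## Template matching

Each track keeps a rolling buffer of appearance crops from the last 0.5 s
of *accepted segmentation detections* (5 crops at 10 fps); the template is
their pixel-wise mean. Restricting buffer updates to segmentation-accepted
frames means the template freezes while the object is occluded instead of
absorbing the occluder. Crops are fixed-size windows (the first
detection's bounding box, clipped to 8–128 px per side) centred on the
accepted measurement — with a fixed window no resampling is needed and no
interpolation blur enters the template.

The SSD map d(u,v) = Σ (f − t)² over all full-overlap placements is
computed by the FFT expansion d = Σ_window f² − 2(f ⋆ t) + Σ t², with the
window sums of f² from a summed-area table and the cross-correlation from
FFT convolution; the map is clamped at 0 against round-off and agrees with
the brute-force double loop to better than 1e-6 relative. The match is
the arg-min placement within ±48 px of the track's predicted position;
ties break toward the previous position, then the smallest (u, v).

Matching operates on a scalar image whose choice is per object kind:
**green channel for blood, luma for instruments**. Hemoglobin absorbs
green, so a blood region is darker in G than anything else in a surgical
scene by a wide margin; in luma, dark tissue texture can match a blood
template almost as well as blood itself, and because the search window
recentres on the prediction each frame, a luma-matched blood template can
"walk" onto dark tissue during an occlusion and drag the track away.
Instruments are uniquely bright in luma, where the same failure mode does
not exist.

A match is only treated as a measurement when its mean per-pixel residual
is ≤ `tmpl_max_mse = 500` (≈ 22 gray levels RMS). An arg-min always
exists somewhere; a poor one means the object is not actually visible, and
feeding it to the filter would both corrupt the estimate and keep dead
tracks alive forever through the lifetime rule.

## Federated tracking

Each track carries two local Kalman filters over a shared 4-state
constant-velocity model (px, py, vx, vy; Q = diag(1, 1, 4, 4) px²,
R₀ = diag(9, 9) px², P₀ = diag(25, 25, 25, 25)): one fed by segmentation,
one by template matching. A *master* estimate fuses the local posteriors
by information weighting, P_m = (P₁⁻¹ + P₂⁻¹)⁻¹,
x_m = P_m (P₁⁻¹x₁ + P₂⁻¹x₂). The reset-free federated variant (no
feedback from master to locals) is used deliberately: a faulty measurement
stream then cannot contaminate the other local, which is the
fault-isolation argument for a federated filter over a single one. A local
that has coasted more than `max_coast = 10` frames (1 s) is excluded from
fusion; with no healthy local the master propagates on prediction alone
(*coasting*), so a live track emits an estimate in every frame — the
behaviour that bridges occlusions. Updates use the Joseph form, which
keeps covariances symmetric PSD over arbitrarily long runs.

Robustness devices around the filters:

* **innovation gate** — a measurement farther than `gate_radius = 64` px
  from the local's prediction is treated as absent (closed gate: the
  boundary accepts).
* **adaptive gain** — R_eff = R₀ (1 + (jump/d_ref)²) with `d_ref = 32`:
  the farther a measurement jumps from the previous position, the less it
  is trusted.
* **area gate** — association also requires the detection's area to be
  within 2.5× of the track's last accepted area. Occlusion-time clutter
  that survives the colour threshold rarely matches the object's size.
* **appearance verification** — an associable segmentation detection is
  cross-checked against the track's template (same residual threshold as
  template matches). This is the federated fault-detection idea made
  concrete: either measurement source can veto a fault in the other. In
  the occlusion scene, occluder fragments that pass the colour threshold,
  the distance gate and the area gate are still rejected here, which is
  what keeps a single within-gate clutter hit from poisoning the velocity
  estimate just before a long coast.

**Association and labels.** Detections are assigned to tracks greedily by
ascending Euclidean distance to the predicted positions (deterministic
tie-breaks: distance, track label, detection x, y), each side used once,
pairs beyond the gate unassigned. Unassigned detections spawn tracks with
fresh labels — never reused — unless they fall within
`spawn_suppression_radius = 64` px of a live track of the same kind
(occlusion-split fragments otherwise mint spurious labels). Hemorrhage
tracking uses the same machinery with a single-region default
(`hemorrhage_max_tracks = 1`); multi-region operation is a config change.

**Lifetimes.** A track spawns at 20 %; each recognized frame (either
source accepted) adds 20 % up to 100 %; a missed frame subtracts
`lifetime_decay` and the track is removed at 0 % ("does not exist"). The
gain rule is fixed; the decay rate is free, and the tracker's default is
4 %/frame rather than a symmetric 20: with symmetric decay a fully
occluded track dies after 5 frames, which contradicts the architecture's
own purpose of bridging multi-second occlusions by estimation. The
standalone `update_lifetime` operation defaults to 20/20 for the scripted
rule checks.

## Flow analysis

The per-frame blood area (pixel count of the fused hemorrhage detection,
0 where absent) is smoothed with a 5-frame moving median (robust to
single-frame smoke/occlusion dips), local extrema of the smoothed series
become knots, and the piecewise-linear interpolation through them —
anchored at the endpoints — is the *trend*. Sliding 30-frame (3 s)
windows are classified by mean trend slope: above `slope_threshold = 10`
px²/frame → *flowing* with a warning; anything else — including a steep
decrease, which indicates a bleed being stanched — → *stagnant*, no
warning. Slopes scale linearly with the series and the classification is
invariant to constant offsets. The threshold and window are qualitative
choices: the reference behaviour distinguishes a near-constant area from
growth of ~75 px²/frame, two regimes separated by an order of magnitude.

## Evaluation

A detection is a true positive when its centroid is within τ = width/15
(42.67 px at 640×480; strictly less-than) of a ground-truth centroid of
the same kind, matched greedily by ascending distance; a matched pair
beyond τ counts as both a false positive and a false negative; leftovers
are FP/FN respectively. Recall = TP/(TP+FN) and precision = TP/(TP+FP)
are reported as undefined (not 0) on empty denominators. Presence
accuracy is the fraction of frames whose binary "any hemorrhage detected"
decision matches truth. RMSE is pooled over all greedy-matched pairs with
*no* distance cutoff — a method that mislocalizes is penalized rather
than silently dropped — and reported per track as well via detection
labels. All distances are in pixels; no physical-unit conversion is
offered because a trustworthy px↔mm scale is not available for this kind
of monocular footage.

## Synthetic scenes

The generator renders what the pipeline's assumptions need and nothing
more: a low-frequency multiplicative texture on a reddish tissue base,
global illumination drift (±3 % sine), small saturated specular discs,
per-pixel Gaussian sensor noise (σ = 3 levels), dark-red blood discs with
scripted area profiles, gray rotated-rectangle instruments on known
trajectories, and scripted occluders (opaque patches or semi-transparent
smoke). Ground truth (median-of-boundary centroid, boundary, exact pixel
area) is taken from each object's rendered mask *before* noise and
occlusion, so tracker behaviour during occlusion is measured against the
true hidden state. Rendering is bit-deterministic given the seed.

The four presets mirror the study conditions: a 200-frame occlusion scene
(blob hidden for frames 100–120 by a reddish patch that the colour
segmenter falsely detects ~95 px away — beyond the innovation gate, so
the tracker must coast); a three-instrument scene with sinusoidal
trajectories, one near-miss and one brief patch occlusion; a stagnant
bleed with a transient dip; and an acute bleed (rapid growth for 50
frames, then plateau and linear decline).

What the presets do *not* emulate: organ pulsation and breathing motion
of the background, camera motion, rolling shutter or MPEG compression
artifacts, blood pooling geometry (discs only), specular streaks on
instrument shafts, and instruments entering/leaving the field of view.
Passing the bundled scenes therefore demonstrates the architecture's
mechanics — segmentability at the stated contrast margins, fusion,
occlusion bridging, label persistence, flow classification — not clinical
performance on real footage, for which the thresholds would need
re-tuning against annotated video.

## Numerical choices and degenerate inputs

Histogram equalization of a constant channel returns it unchanged.
`k` exceeding the number of distinct colours raises a degenerate-cluster
error (checked cheaply on a pixel probe, fully only when the probe looks
degenerate). An empty frame directory is an empty sequence, not an error.
SSD values are clamped at 0; exact embeds are recovered at 1e-6
tolerance. Fusion inverts covariances directly (4×4); singular
covariances raise. Tie-breaks are deterministic everywhere (documented
per operation), so identical inputs give byte-identical outputs, which
the pipeline asserts by embedding a config hash and seed in every
artifact.

## Problem sizes

All bundled scenes are 200 frames at 640×480 — 20 s of video at the
reference rate, enough to contain each scripted event (occlusion windows,
growth/decline phases) with surrounding steady-state tracking. The test
suite and the acceptance script run each preset once end-to-end
(~0.1–0.25 s per frame per kind on one CPU).

## Known limitations

* Track identity is not re-established after death: a reborn object gets
  a fresh label (no appearance re-identification).
* Template size is fixed at first detection; objects that grow far beyond
  it are still tracked (the window rides the measurement) but the
  template describes only their central region.
* The flow classifier reads total blood area; camera zoom or motion would
  masquerade as flow.
* Appearance verification assumes the template channel separates object
  from clutter; an occluder with the object's own colour statistics would
  pass it and must be caught by the distance/area gates instead.
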