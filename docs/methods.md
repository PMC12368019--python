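# Methods

This note documents the models, algorithms and numerical choices behind the
package, the synthetic data it is validated on, and the limits of what those
validations show.

## Tracking model

The face is treated as a textured surface imaged by a fixed camera at known
frame rate; consciousness-relevant movements appear as small, spatially
coherent displacements of skin texture inside a command's region of interest
(ROI). Landmarks are skin pores: dark blobs a few pixels across, detected on
the reference frame by an inverted difference-of-Gaussians band-pass matched
to the pore radius (default 1.5 px), local-maximum selection with a minimum
separation (default 3 px), and quadratic sub-pixel refinement.

Tracking is sparse pyramidal Lucas–Kanade, **anchored to the reference
frame**: each landmark carries a 9×9 template from frame 0, and every later
frame is registered to that template by Gauss–Newton iterations on the
photometric error (bilinear sampling; template gradients precomputed, so the
2×2 normal equations invert once per landmark), coarse-to-fine over a
2-level Gaussian pyramid, initialized at the previous frame's estimate.
Anchoring matters: chaining frame-to-frame estimates accumulates a random
walk of registration noise (~0.05 px/step grows to >1 px over a
half-hour session), which would swamp the sub-pixel signals of interest.
The cost is that appearance change over time (lighting, occlusion) shows up
as residual error; landmarks whose mean absolute residual exceeds 10 gray
levels, or that approach the frame border, are marked lost and are not
re-acquired — re-acquisition risks identity switches that corrupt trial
statistics. Convergence tolerance is 0.03 px with at most 10 iterations per
level; on the synthetic scenes this is indistinguishable from a 0.01-px/20-
iteration setting while ~35% faster.

Rigid whole-face motion (bed/camera bumps) is estimated per frame as the
component-wise median displacement over all valid landmarks and subtracted.
The median is robust while genuine responses move well under half of the
landmarks (the eye ROI holds ~25% of landmarks in the default scene;
measured response attenuation is below 15%). Frames whose pre-subtraction
median magnitude exceeds 1 px are flagged as artifacts; trials overlapping
a flagged frame are excluded from positivity (they still count toward the
trial total), mirroring the blinded raters' artifact rule.

Coordinates are 0-based pixels, x rightward, y downward; time is
frame_index / fps.

## Trial statistics

The ROI trace is a movement *rate*: the per-frame sum over valid inside-ROI
landmarks of the frame-to-frame displacement magnitude. A rate returns to
baseline between commands, matching how session traces are read; summing
cumulative positions instead would integrate sustained posture changes
indefinitely.

Each command presentation is tested by comparing the trace distribution in
the 20-s pre-onset baseline against the 20-s response window with the
two-sample Kolmogorov–Smirnov statistic, plus a post-peak amplitude
(response maximum minus baseline median, floored at zero). Window indices
follow the convention baseline `[onset−20 s, onset]`, response
`(onset, onset+20 s]` (at 30 fps and onset 60 s: frames 1200–1800 and
1801–2400). A trial's baseline is clipped so it never overlaps the previous
trial's response window; truncated final trials are kept only if at least
half the response window remains. Segments shorter than 5 frames are
rejected as too unstable for an ECDF comparison.

**KS gate interpretation.** The published decision rule reads "KS statistic
< 0.1 and post-peak amplitude > 400" while also stating that the KS number
grows with the size of the movement change. A *small* two-sample D means
the distributions are *similar*, so the literal reading contradicts the
stated semantics. The default mode therefore applies the 0.1 threshold to
the KS **p-value** (p < 0.1 ⇒ the response window differs from baseline); a
`raw_d` mode (positive when D > 1 − 0.1) is provided for the literal
reading. Which variant the original clinical implementation used is not
publicly documented; neither mode is presented as certified. Thresholds are
strict inequalities — values exactly at a gate are negative.

**Amplitude gate units.** The 400 gate is in pixel-summed units that depend
on zoom and landmark count; it is preserved as the default for fidelity
with the clinical pipeline. For synthetic scenes a normalized mode divides
the trace by the valid ROI landmark count and gates at 0.12 px/frame per
landmark, ≈2.4× the measured per-landmark step-noise ceiling (~0.05
px/frame) at the default scene settings — calibrated once from the
resting-baseline noise floor, which is what the opening baseline minute is
for.

A video is SeeMe+ when at least 3 of its 10 trials are positive;
contaminated trials can never be positive but count toward the total.

## Synthetic sessions

No public video of unresponsive patients exists, so validation uses a
generator with exact ground truth. It emulates: a smooth-shaded plane with
~0.2 mm/px pore texture (seeded placement, ≥6 px separation so every pore
is detectable), polygonal eye/mouth ROIs, stimulus-locked micro-movements
warped into an ROI (uniform displacement with a 2.5-px linear taper
*inside* the polygon edge, so no injected motion leaks outside the
declared ROI), i.i.d. Gaussian pixel noise (default sd 2 gray levels), and
transient whole-frame translations as camera-bump artifacts. Waveforms:
smooth ramp–hold–release (default; 30% rise/release), Gaussian bump, and a
two-cycle sinusoid for sub-pixel fidelity sweeps. Real evoked-movement
kinematics (latency and velocity distributions) are unpublished; these
defaults are placeholders and are flagged as such.

What the generator does **not** emulate: 3-D head pose and rotation,
non-rigid skin deformation outside the ROI, lighting changes, occlusion
(endotracheal tubes, clinicians entering the frame), compression artifacts,
or realistic facial appearance. Passing tests therefore demonstrate the
correctness and sensitivity of the algorithmic chain on its stated motion
model — not clinical performance on patient video.

Study-scale experiments (in `seeme.experiments`) use 160×160 px frames at
5 fps with the clinical presentation protocol intact (60-s baseline, blocks
of ten, 30–45 ± 1 s gaps): a null study of 20 sessions (200 command
presentations with no injected response) for false-positive control, and an
amplitude sweep at 0.5/1/2/4 px for power and recovery. At these settings
the measured false-positive rate is dominated by the KS gate's nominal 10%
level and is cut to ~0 by the amplitude gate; power reaches 1.0 at 2 px.
Amplitude recovery uses the per-landmark **median** displacement inside the
ROI, which is robust to the tapered boundary minority and unbiased by
tracking noise (noise enters in quadrature only); the mean-based variant
remains available and runs ~8% low at the default taper.

## Clinical analyses

Detection timelines use integer days from injury; multiple sessions on one
day collapse to the day's best result, and same-day detection gives lead
time 0. Eye commands are matched to GCS-E > 2 (eye-opening to voice or
spontaneously — GCS is used because it separates this from eye-opening to
pain), mouth commands to CRS-R auditory > 2 (reproducible command
following). Lead time is defined only when both detections exist; cohort
summaries report mean ± SD per stratum.

Rater decisions follow the either-rater rule per trial and the 3-of-10 rule
per video; agreement is percent agreement plus Cohen's kappa with chance
correction from the marginals (undefined, returned as NaN, when both raters
are single-label). The statistics suite wraps tie-corrected Kruskal–Wallis,
Dunn's pooled-rank z-tests with Bonferroni correction over all k(k−1)/2
pairs, Pearson chi-square without continuity correction, rank-based AUC
(ties count ½, invariant under monotone transforms), and a one-sample KS
normality check whose p-value carries a caveat flag because the normal
parameters are estimated from the same sample (conservative; harmless when
used only to justify rank tests).

Sedation is classified from infusion rates: light below, deep at/above
50 µg/kg/min propofol (35 when dexmedetomidine ≥ 0.5 µg/kg/h, reflecting
their synergy), 0.7 µg/kg/h dexmedetomidine, 0.1 mg/kg/h midazolam,
1.5 µg/kg/h fentanyl; "none" without any non-zero infusion. The published
dexmedetomidine light range is printed in µg/kg/min although the combined
propofol rule uses µg/kg/h; rates here are stored and validated in µg/kg/h
(the clinically standard unit) and the discrepancy is surfaced rather than
silently corrected. Boundary values (e.g. propofol exactly 50) fall on the
deep side, keeping the rule monotone in every dose.

## Command classifier

Feature sequences are per-frame landmark step magnitudes pooled on a fixed
spatial grid (default 4×4), so videos with different landmark counts share
one dimensionality; sequences cover the 20-s response window, zero-padded
at video end. The classifier is a single bidirectional LSTM layer (hidden
width 24 per direction), mean-pooled over time, with one fully connected
projection and softmax — implemented in numpy with manual backpropagation
(gradients are verified against finite differences in the tests), trained
full-batch with Adam (lr 0.02, gradient-norm clip 5, 80 epochs). All
initialization and augmentation is seeded, so training is bit-deterministic.

Class balancing uses label-preserving augmentation (temporal shift up to
~1 s, additive feature noise at 5% of the sample's scale, amplitude scaling
0.9–1.1), applied to the training partition only; augmented copies whose
source trial lands in the test partition are discarded, and splits are
grouped by source trial, so no trial information leaks across the boundary.
The published per-command accuracies (81/37/47%, 65% overall) depend on
patient data and trained weights that are not available; they are context,
not reproduction targets. The desk-scale claim tested here is specificity:
on synthetic command-specific sequences the classifier must be far above
chance, and at chance on label-shuffled data.

## Degenerate inputs and tie-breaks

Zero pore density yields a featureless frame with a warning (not an error);
a blank frame yields an empty landmark set likewise. An ROI containing no
landmarks raises an error naming the ROI. Identical samples give KS D = 0,
p = 1; all-identical groups give Kruskal–Wallis H = 0, p = 1. Landmarks
with a singular structure tensor (textureless patches) are marked lost at
frame 0. Ties at decision thresholds resolve to negative throughout.

## Known limitations

- The exact pore-tagging/tracking algorithm and the KS variant of the
  original clinical pipeline are not publicly documented in full; the
  contracts here are a documented interpretation.
- The amplitude gate's clinical units (the 400 threshold) cannot be
  reproduced without the original optics; the normalized mode is the
  portable equivalent.
- Compressed video containers (MP4/AVI) require an imageio ffmpeg plugin;
  PNG sequences and TIFF stacks are supported natively.
- The synthetic face model is planar; results do not certify robustness to
  pose change, occlusion or lighting, and clinical performance claims are
  out of scope.
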