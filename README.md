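# seeme

Detection of low-amplitude, stimulus-evoked facial movements in video of
unresponsive brain-injury patients.

After acute brain injury, some patients who look unresponsive at the bedside
are nonetheless processing commands — their evoked movements are simply too
small or inconsistent for the naked eye. This package implements a
computer-vision pipeline for that problem: it tags pore-scale features on the
face (at ~0.2 mm resolution one pixel covers a skin pore), tracks them
sub-pixel through the session video into a displacement vector field, and
tests each spoken-command presentation for a stimulus-locked change in
movement. It is aimed at researchers studying covert consciousness /
cognitive–motor dissociation who need a transparent, fully testable
reimplementation of the method, together with the surrounding clinical
analyses (detection timelines vs. GCS/CRS-R, blinded-rater agreement, outcome
statistics, sedation classification) and a synthetic-session generator that
makes every stage verifiable without patient data.

## Method

A session video starts with a 1-minute resting baseline, followed by one
spoken command ("Open your eyes", "Stick out your tongue", "Show me a smile")
presented in a block of ten with 30–45 s (±1 s jitter) between presentations.
The pipeline:

1. **Pore tagging and tracking.** Dark pore-like blobs are detected on the
   reference frame by difference-of-Gaussians band-pass and tracked through
   every frame with a pyramidal Lucas–Kanade patch registration anchored to
   the reference template, giving per-landmark displacements `d_i(t) ∈ R²`
   at sub-pixel precision. The per-frame median displacement over all
   landmarks estimates rigid camera/bed motion; it is subtracted, and frames
   where it exceeds a threshold are flagged as artifacts.
2. **ROI trace.** For the command's region of interest (eyes or mouth
   polygon), the movement trace is the landmark summation
   `x(t) = Σ_{i∈ROI} ‖d_i(t) − d_i(t−1)‖`.
3. **Trial decision.** For each presentation at onset `t₀`, the baseline
   segment `[t₀ − 20 s, t₀]` and response segment `(t₀, t₀ + 20 s]` are
   compared with the two-sample Kolmogorov–Smirnov statistic
   `D = sup_x |F_base(x) − F_resp(x)|`, and the post-peak value
   `max(resp) − median(base)`. A trial is positive when the KS gate passes
   (default: p < 0.1) **and** the post-peak exceeds its amplitude gate
   (400 in the clinical pixel-summed units, or a per-landmark normalized
   gate for synthetic scenes). A video is **SeeMe+** when ≥ 3 of 10 trials
   are positive.
4. **Clinical comparison.** Per-patient timelines compare the first SeeMe+
   day against the first day with GCS eye subscore > 2 (eye commands) or
   CRS-R auditory subscore > 2 (mouth commands). Outcome analyses use
   Kruskal–Wallis with Dunn–Bonferroni post-hoc tests, chi-square tests,
   rank AUC, and Cohen's kappa for blinded-rater agreement.
5. **Command classification.** A bidirectional LSTM over per-frame landmark
   displacement features (with class balancing by label-preserving
   augmentation and an 80/20 trial-grouped split) tests whether detected
   movements are specific to the command presented.

## Worked example

`examples/simulate_and_detect.py` builds a synthetic session with three
"open your eyes" presentations and 3-px micro-movements injected in the eye
ROI, and runs the full chain:

```
session: 526 frames at 5 fps
trial  KS D    KS p      post-peak  positive
    1  0.372  1.20e-06      0.198  True
    2  0.309  1.19e-02      0.207  True
    3  0.283  1.33e-02      0.201  True
video: 3/3 positive trials -> SeeMe+
```

Each injected movement shifts the response-window movement distribution
(KS p below 0.1) and lifts the post-peak (px/frame per landmark, normalized
mode) above the 0.12 gate, so all three trials are positive and the video is
SeeMe+. The other scripts in `examples/` demonstrate the outcome-statistics
suite, rater agreement (the 4/1/1/4 disagreement table giving kappa = 0.60),
the BiLSTM command classifier (test accuracy 1.00 on the separable fixture,
0.47 on a label-shuffled control with 15 test trials), and the sedation rule
table.

There is also a CLI for shell use: `seeme simulate`, `seeme run`,
`seeme rate`, `seeme stats`, `seeme classify-commands` (see `seeme --help`).

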