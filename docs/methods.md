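# Methods

This note documents the models, numerical choices and limitations behind
`cusdvt`, in the order the pipeline runs: synthetic data → triple-task
network → exam protocol → evaluation statistics → health-economic model.

## Synthetic compression-ultrasound sequences

No public compression-ultrasound DVT dataset exists, so the package ships a
generator whose outputs carry exact ground truth. A scene is a set of
vessel cross-sections on a 150×150 grid, drawn from a per-landmark
archetype table that encodes each anatomical location's vessel arrangement
(e.g. LM3: the common femoral vein with the superficial and deep femoral
arteries → one vein and two arteries; LM8: popliteal vein and artery; the
saphenofemoral junction LM1: a small superficial vein over the large common
femoral vein). Archetype positions are jittered ±3 px and sizes ±10% per
seed; vein lumina are dark (echogenicity drawn in [0.08, 0.20]) on a bright
tissue background (0.55), with multiplicative low-pass-filtered speckle
(grain 1.5–2.5 px, contrast 0.25–0.45) applied to frames only — masks are
exact rendered ellipse interiors.

Compression physics is deliberately minimal and axial. Probe pressure is a
dimensionless per-frame scalar in [0, 1] (no pressure calibration is
available to anchor physical units). A healthy vein's vertical semi-axis is
`b·max(0, 1 − p/p_collapse)` with the collapse pressure drawn in
[0.5, 0.8], so a ramp to full pressure always closes it; the lateral axis
is fixed. A thrombosed vein never shrinks below a residual fraction of its
resting height (default 0.5, never below 0.3). Arteries pulsate within
±10% of their resting height and never close. The default pressure profile
settles at zero for ~15% of the clip (the operator finding the landmark),
ramps up over ~35%, holds peak for ~20% and releases — a medium-paced
compression.

A frame is labelled **closed** when the total vein mask area is at most 5%
of its rest-state area (`closed_area_fraction`, configurable); the label is
therefore recomputable from each frame's own mask. Scenes without a vein
(pure background) have no meaningful open/closed state; they are labelled
"open" for type stability but carry **zero weight in the compression loss**
— an empty segmentation mask genuinely cannot distinguish "no vein here"
from "vein fully compressed", and training on the arbitrary label poisons
the open/closed head (see Limitations).

Datasets are planned as manifests of per-sequence seeds: every sequence is
regenerable bit-identically, and the validation split is drawn at the
subject level so no subject straddles the split. Training-time
augmentation applies one shared geometric transform per window (random
left/right flip, ±15 px translation, ±15° rotation, zoom up to a factor of
0.05) to all nine frames and the mask (nearest-neighbour for the mask,
bilinear for frames) plus an intensity rescale within ±0.3 on frames only,
clipped to [0, 1].

What the generator does **not** emulate: acoustic wave propagation,
shadowing and dorsal enhancement, device-specific image dialects, probe
motion and out-of-plane anatomy, non-echogenic thrombi. Passing tests on
this data demonstrate that the architecture, losses, protocol logic and
statistics are implemented coherently and can be learned end to end — not
clinical performance on real ultrasound.

## Triple-task network

Input is a sliding window of nine consecutive frames (one window per frame,
advancing by one; the first eight windows replicate the first frame on the
left so every frame receives an output). The backbone is a U-Net-style
encoder/decoder over the 9-channel stack: a stem convolution to the base
width, then per level a stride-2 convolution doubling the width and a 3×3
convolution, with the decoder mirroring via nearest-neighbour upsampling,
skip concatenation and 3×3 convolutions; a 1×1 head produces the 3-class
(background/artery/vein) softmax for the last-most frame.

Two auxiliary branches make it triple-task:

- the **landmark branch** reads the bottleneck pooled to a 2×2 spatial grid
  (a global pool would discard the left/right and shallow/deep arrangement
  that distinguishes landmarks) through a dense softmax layer over the
  regional landmark classes plus background;
- the **open/closed branch** reads the output segmentation mask — per-block
  class-area fractions (4×4 grid, rescaled ×20 to O(1)) concatenated with
  per-block peak class probabilities, through a 16-unit ReLU layer to a
  sigmoid. The peak features keep a faint residual lumen (below the 0.5
  level) distinguishable from a truly closed vein; the artery/background
  channels keep a closed-vein mask distinguishable from a vessel-free
  scene. Using the predicted probability map rather than a hard mask keeps
  the whole graph differentiable end to end.

Two regional models with identical architecture are trained: groin/thigh
(LM0–LM5 + background) and knee (LM8–LM10 + background). For reporting and
for the exam protocol, landmark posteriors are consolidated by summing
member classes into the groups LM0–LM1, LM2–LM3–LM4, LM6–LM7 and
LM8–LM9–LM10.

Losses: segmentation uses mean binary cross-entropy over pixels and classes
of the one-hot mask; the landmark term is BCE summed over classes (averaged
per sample); the open/closed term is a scalar BCE. The composite is
`α·L_seg + β·L_lm + γ·L_oc` with α=100, β=γ=1. Probabilities are clipped
at 1e-7 before logarithms. Optimisation is Adam with momentum β₁=0.9
(β₂=0.999), default learning rate 1e-3 and batch size 8; training windows
are re-augmented every epoch with the translation range scaled to the
internal resolution.

The implementation is a small reverse-mode autodiff over numpy
(`cusdvt.nn`): im2col/col2im convolutions, dense layers, channel softmax,
grid mean/max pooling, clipped-BCE reductions. Parameters and activations
are float32 (CPU throughput); the ops preserve dtype, so float64 graphs —
used by the finite-difference gradient check — work unchanged. Gradients
agree with central finite differences to well under 1e-3 relative error.

The network runs at a configurable internal resolution (inputs resized
bilinearly with anti-aliasing on the way down, segmentation probabilities
resized back to 150×150 and renormalised on the way out), so the window
contract stays 150×150 while desk-scale models stay fast. The documented
default configuration is 4 levels / base width 32 at 144×144; the
desk-scale study configuration is 2 levels / base width 8 at 48×48
(~28k parameters). Matching any particular published parameter count is a
non-goal.

A naive sequence classifier is included as the comparison baseline: a small
convolutional encoder trained on the per-frame open/closed task provides
128-dimensional frame embeddings, which are stacked along time (padded or
cropped to a fixed length) and classified healthy/pathological by a 3-layer
1-D CNN. It sees no segmentation supervision and makes no per-frame claims
— exactly the black-box design the explainable pipeline is meant to beat.

## Exam protocol

The two-point exam requires three adequate compressions: two in the groin
(groups LM0–LM1 and LM2–LM3–LM4) and one at the knee (LM8–LM9–LM10). A
sequence's verdict at its target group is:

- **inadequate** if fewer than τ_lm = 0.5 of windows have their
  consolidated-landmark argmax at the target group;
- otherwise **compressible** if closure is detected: the closed posterior
  stays ≥ τ_closed = 0.5 for k = 3 consecutive windows, **or** the
  predicted vein area (pixels with vein probability ≥ 0.5 — counting,
  rather than summing raw probabilities, avoids dilution by diffuse
  background mass) falls to ≤ ε = 0.05 of its in-sequence maximum;
- otherwise **non-compressible**.

The two closure gates combine with a configurable OR (the posterior gate
carries learned appearance evidence; the area gate is robust where a
single final mask is intrinsically ambiguous, e.g. one-vein landmarks whose
closed state is an empty mask). All thresholds sit in
`ProtocolThresholds`.

Per group, attempts repeat until a compressible verdict or the attempt cap
(default 3, the range 3–5 is supported); after the cap the group keeps the
worst informative verdict — non-compressible dominates inadequate, so a
vein seen resisting pressure is never downgraded by a later badly-imaged
attempt. Patient level: all three groups compressible → DVT excluded; any
non-compressible group → suspected DVT; otherwise → incomplete exam with a
referral recommendation. A continuous patient score for ROC analysis is
the maximum over groups of (1 − best closed posterior); this scalar is this
package's own construction (monotone in each group's evidence), since only
the categorical decision is published.

Temporal quality heuristics (vein visibility, border proximity, compression
pace within a window band) flag operator problems; they gate nothing by
default.

## Evaluation statistics

F1 = TP/(TP + (FP+FN)/2); per-label Sørensen–Dice = 2TP/(2TP+FP+FN) over
pixels; bounding-box IoU over axis-aligned label boxes, with the exact
set identity IoU = F1/(2−F1) exposed for cross-checking. Undefined metrics
(label absent from both masks, empty class) raise a typed error rather than
returning 0, so per-label averages cannot be silently biased. When a
validation *set* is scored, Dice is aggregated by pooling pixel counts
across frames (micro), not by averaging per-frame ratios — per-frame Dice
on a nearly-closed vein of a few pixels is noise, not signal.

Predictive values are prevalence-adjusted by Bayes' rule so enriched
case-control validation sets report patient-relevant numbers. ROC curves
sweep unique score thresholds with ties grouped, making the trapezoidal AUC
equal the Mann–Whitney concordance probability; the operating threshold
maximises Youden's J = TPR − FPR with ties broken toward higher
sensitivity. Cross-validation summaries use mean ± z·SD/√k (normal
approximation, sample SD), truncated to [0, 1] for rates.

The power analysis inverts the noncentral-t power function of a two-sample
t-test, iterating n upward; the default one-sided setting at Cohen's
d = 0.5, α = 0.05, power 0.8 yields 51 patients per group (the two-sided
variant yields 64; one-sided is the setting that matches the published
minimum, and both are available).

## Health-economic model

Diagnostic strategies are decision trees over tests (Wells score as a
three-way categorical split conditional on DVT status; D-dimer with its
specificity conditional on the Wells category; specialist proximal
ultrasound; the ML-guided exam) and treat/no-treat leaves. Outcome
likelihoods come from exact enumeration over DVT status × test-result
paths (no simulation), assuming conditional independence of test errors
given DVT status except the documented D-dimer/Wells coupling. Default
prevalence is 14.7% (a clinic-referral estimate; the alternative 7.1%
general-clinic figure is a config value).

Each diagnostic-accuracy outcome (TP/FP/TN/FN) carries lifetime discounted
QALYs and costs (payoffs pre-discounted at 3.5%/yr; not recomputed).
Expected cost adds per-test administration costs weighted by usage and the
software price `c` once per ML-guided exam, so
`NMB(c) = λ·ΔQALY + (cost_without − cost_with(c))` is affine in `c` with
slope −(ML-exam usage); break-even prices follow in closed form. ICERs
flag dominance quadrants instead of dividing by ~0 (|ΔQALY| < 1e-9 reduces
to cost minimisation).

Payoffs can be re-derived from event-level parameters: QALYs =
base-QALE·(1 − Σ p_fatal − Σ p_nonfatal·(1 − utility multiplier)), events
combined additively (a mutually-exclusive approximation; the exact
composition behind the published payoff table is not printed, so
re-derivation is checked to a 0.15-QALY tolerance, not asserted exactly).
Costs sum event costs plus the £845 treatment cost where treated.

Parameter uncertainty: every parameter carries its published distribution
(beta, gamma with mean = shape·scale, Dirichlet counts, or fixed). At load
time each analytic mean is cross-checked against the printed point
estimate (tolerance 0.005 absolute or 0.5% relative); four published rows
are internally inconsistent — the treated-DVT fatal-PE beta (printed mean
0), the warfarin "no haemorrhage" 0.98 vs the count-implied 0.974, and the
Wells and ultrasound cost gammas — and these raise warnings and are marked
flagged rather than silently used. Deterministic runs use printed means
(Dirichlets use count-implied means so splits stay proper distributions);
the PSA samples the printed parameters, keeps the treated fatal-PE
probability at its printed zero, re-derives payoffs per draw, and
summarises cost/QALY/NMB with 95% quantile intervals and P(NMB > 0).

The pathway presets (a = the current Wells → D-dimer → ultrasound
algorithm; b–d = the ML exam as a rule-out/triage step at different points;
e–f = more ultrasound-intensive roles) are explicit, serialisable JSON
trees intended to be inspected and edited — the published figures do not
print full branch structure, so no preset claims branch-exact fidelity,
and reproducing absolute pathway costs is out of scope.

## Desk-scale study configuration

The end-to-end acceptance check trains both regional models on 140 clean
(speckle-free) sequences from 20 synthetic subjects (landmark mix weighted
toward the common groin/knee landmarks, 25% thrombosed, 10% subject-level
validation split, 20-frame profiles), at 48×48 internal resolution with 2
levels and base width 8, for 45 epochs of Adam (lr 1.5e-3, batch 16, 6
windows per sequence, full augmentation), then scores held-out subjects
(micro vein Dice, open/closed macro-F1 over vein-bearing sequences,
consolidated-landmark macro-F1) and runs complete exams on 20 fresh
synthetic patients. The whole check runs in roughly ten minutes on one CPU
core.

## Known limitations

- The simulator's appearance model is geometric, not acoustic; domain
  transfer to real ultrasound is explicitly out of scope.
- A single final-frame segmentation mask cannot signal compression at
  landmarks whose only vessels are veins (a closed vein and an absent vein
  are both an empty mask); the protocol's area gate covers this case, and
  the open/closed head is simply not trained on vessel-free scenes.
- The pressure scale is dimensionless; compression "speed" is frames, not
  seconds.
- Landmark archetypes are single canonical layouts with jitter; real
  anatomical variability (duplications, depth variation, adjacent
  structures) is far richer.
- The economic pathway presets approximate unprinted branch structures;
  their absolute costs should be read as model outputs, not reproductions.
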