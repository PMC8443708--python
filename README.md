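# cusdvt

A toolkit for machine-learning-guided **compression ultrasound (CUS)** exams
of the leg veins, the gold-standard manoeuvre for diagnosing proximal
**deep vein thrombosis (DVT)**: probe pressure collapses a healthy vein,
while a vein that will not compress harbours a clot.

The package is aimed at researchers prototyping ML-guided point-of-care DVT
screening — it contains the full computational chain of such a system, with a
ground-truthed simulator standing in for (unreleasable) patient imaging:

- **`cusdvt.synth`** — a seeded synthetic CUS simulator: eleven anatomical
  landmarks (LM0–LM10) along the femoral and popliteal veins, each with its
  characteristic arrangement of compressible veins and pulsating arteries,
  rendered as dark elliptical lumina on a speckled 150×150 B-mode frame under
  a dimensionless probe-pressure profile, with exact per-frame masks and
  open/closed labels. Thrombosed veins retain a residual lumen under any
  pressure — the physical signature the rest of the pipeline must recover.
- **`cusdvt.net`** — a triple-task network on 9-frame sliding windows: a
  U-Net-style encoder/decoder segments background/artery/vein in the
  last-most frame, a landmark branch classifies the anatomical location from
  the bottleneck, and an open/closed branch scores vein compression from the
  output segmentation mask. The composite loss is
  `L = α·L_seg + β·L_lm + γ·L_oc` with defaults α=100, β=γ=1 (binary
  cross-entropy throughout), optimised by Adam with momentum 0.9. The
  network and its reverse-mode autodiff live entirely on numpy
  (`cusdvt.nn`), so everything runs on a plain CPU.
- **`cusdvt.protocol`** — the two-point exam automaton: per-sequence
  compression verdicts at the consolidated landmark groups LM0–LM1,
  LM2–LM3–LM4 (groin) and LM8–LM9–LM10 (knee), an attempt loop (default
  three attempts per group), and the patient decision — three fully
  compressible groups exclude DVT; any resisting vein flags a suspected DVT;
  anything else is an incomplete exam with a referral recommendation.
- **`cusdvt.metrics`** — F1, per-label Sørensen–Dice, bounding-box IoU (with
  the identity `IoU = F1/(2−F1)`), sensitivity/specificity/accuracy,
  prevalence-adjusted PPV/NPV, ROC/AUC with Youden-optimal thresholds,
  cross-validation fold CIs, and a noncentral-t power analysis.
- **`cusdvt.rubric`** — the 10-criterion expert image-quality score
  (total 10–35; sequences with total ≤ 20 are accepted).
- **`cusdvt.econ`** — a decision-tree cost-effectiveness model of DVT
  diagnostic pathways (Wells score, D-dimer, specialist ultrasound, ML-guided
  exam) with lifetime QALY/cost payoffs per diagnostic-accuracy outcome,
  net monetary benefit `NMB(c) = λ·ΔQALY + Δcost` as a function of the
  software price per exam, ICERs, and probabilistic sensitivity analysis
  over the published beta/gamma/Dirichlet parameter encodings.

## Worked example

Simulate a knee-landmark compression, run the exam automaton on the
simulator's own ground truth, and evaluate the economic model:

```python
import numpy as np
from cusdvt import synth, net, protocol, econ, metrics

# a healthy popliteal cross-section under a compress/hold/release profile
scene = synth.make_scene("LM8", pathology=False, seed=3)
seq = synth.render_sequence(scene, synth.ramp_profile(), seed=3)
print(seq.open_closed.count("closed"), "closed frames of", seq.n_frames)

outs = protocol.oracle_outputs(seq, net.KNEE.class_names)
verdict = protocol.sequence_verdict(outs, "KNEE", net.KNEE.class_names)
print(verdict.status, round(verdict.min_area_ratio, 3))

# minimum patients per group for 80% power at Cohen's d = 0.5 (one-sided)
print(metrics.power_min_n(d=0.5, alpha=0.05, power=0.8, sides=1))

# expected QALYs of the current clinical pathway's outcome mix
params = econ.load_params(warn=False)
lik = dict(params.table6_rows["no_software_support"])
r = econ.expected_outcomes(lik, {}, params.payoffs, {},
                           econ.EconConfig(prevalence=lik["tp"] + lik["fn"]))
print(round(r.expected_qalys, 2))
```

Output:

```
9 closed frames of 20
compressible 0.0
51
11.57
```

The healthy vein closes fully at peak pressure (nine closed frames, minimum
vein-area ratio 0), so the exam automaton calls the sequence compressible;
the power analysis returns 51 patients per group; and weighting the
published outcome likelihoods by their lifetime QALY payoffs gives 11.57
expected QALYs per patient.

Training a desk-scale model pair end to end (a few minutes on one CPU core):

```python
manifest = synth.make_dataset({
    "landmarks": {"LM8": 18, "LM9": 16, "LM10": 16, "background": 10},
    "n_subjects": 12, "pathology_fraction": 0.25, "val_fraction": 0.1,
    "n_frames": 20, "speckle": False, "seed": 11})
model = net.build_model("knee", {"levels": 2, "base_width": 8,
                                 "resolution": 48}, seed=11)
history = net.train(model, manifest, {"epochs": 20, "lr": 1.5e-3,
                                      "batch_size": 16, "seed": 11})
```

There is also a thin CLI (`cusdvt simulate|train|exam|evaluate|econ|qc`);
run `cusdvt --help` for the subcommands.

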