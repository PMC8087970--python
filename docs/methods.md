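# Methods

This note records the models, conventions and design choices behind
`ecgplace`, in the order the pipeline runs.

## Synthetic cohort model

Real paired correct/misplaced recordings require a dense body-surface
potential map per patient, and no such corpus is public. The generator
replaces it with a parametric single-beat model whose ground truth is known
exactly.

**Waveform.** One cardiac cycle of duration 0.6 s at 300 Hz (180 samples).
The noiseless beat is a sum of Gaussian bumps, one per wave:
P (0.15 mV at 0.12 s), Q (−0.10 mV at 0.26 s), R (1.20 mV at 0.30 s),
S (−0.50 mV at 0.36 s), widths 25/10/14/14 ms. V1 shares the subject's
parameters with an overall gain of 0.75 and per-wave shape factors
(relatively smaller P, deeper Q/S, stronger r') so that the two leads are
correlated but not proportional — otherwise the inter-lead correlation and
RMS-difference features would be degenerate after per-lead normalization.

**Subject classes.** Three diagnostic classes with equal counts: normal
(nominal amplitudes), myocardial infarction (R x 0.55, Q x 2.5, S x 0.8 —
reduced ventricular forces with a deepened Q) and left ventricular
hypertrophy (R x 1.5, S x 1.4). Per-subject variation is a shared
beat-size factor (lognormal, sigma 0.15) times small independent per-wave
factors (sigma 0.07), a whole-complex timing shift (sigma 4 ms) and width
factors (sigma 0.06). Variation is deliberately dominated by the common
gain: that is how electrode contact and body habitus act on a real beat,
and it keeps the R/S amplitude ratio — and hence the identity of the
dominant deflection — stable within a class.

**Misplacement effect.** Placing V1/V2 one ICS too high (3rd ICS,
severity 1) multiplies R by (1 − 0.045·e), S by (1 − 0.036·e), shifts P
down by 0.024·e mV and adds an r' bump of 0.036·e mV at 0.40 s, where e is
the cohort's `effect_scale` (default 1). Two spaces too high (2nd ICS)
applies the same deltas at severity 2. At `effect_scale = 0` the misplaced
distribution equals the correct one exactly. The base delta magnitudes
were calibrated once so that, at the default noise level and desk-scale
cohort sizes, the best model's held-out accuracy sits in the
mid-0.9s for the 2nd-ICS condition and distinctly lower (roughly 0.6–0.85)
for the 3rd-ICS condition — ordered and away from both ceiling and chance,
which is the statistical regime the generator is meant to emulate. These
effect sizes are free parameters of the generator, not estimates of any
recorded cohort.

**Noise.** Additive white Gaussian noise, default SD 0.05 mV (a realistic
residual for a filtered single beat), plus a 0.4 Hz sinusoidal baseline
drift of 0.05 mV with random phase.

**Randomness.** Each subject's stream is seeded by
`(seed, class, subject_index)`, so enlarging a cohort never reshuffles the
subjects already in it, and cohort serialization is byte-identical across
runs with the same config.

**What the generator does not emulate.** Real torso geometry and the
continuous dependence of morphology on electrode coordinates; beat-to-beat
variability (one beat per recording by design); T waves; pathologies beyond
the two stylized classes; horizontal misplacement or limb-lead swaps.
Passing tests therefore demonstrate that the pipeline recovers *this*
generative structure, not clinical performance.

## Preprocessing

Normalization is `y[n] = s[n]/max|s[n]|`, applied per lead; it is
idempotent and scale-invariant, and it preserves landmark indices.

Delineation runs on the raw beat. The R peak is the global absolute
extremum. QRS onset/offset are the first samples, scanning outward from R,
where the rectified first difference stays below 10% of its maximum for 3
consecutive samples; the difference signal is computed on a 5-sample
moving-average copy so measurement noise does not mask the quiet baseline,
and if no quiet run exists the bound falls back to a physiological window
(80 ms before / 120 ms after R). The P peak is the absolute extremum before
QRS onset; the S trough is the minimum between R and the QRS offset.

The PR interval is measured P-peak-to-QRS-onset in ms. P *onset* is
ill-posed on noisy single beats; the peak-to-onset distance is robust and
monotone in the same physiology.

## Features

Sixteen features per beat pair (IDs f1–f16). Conventions that the numbers
depend on:

* Single-lead features (f1–f14) use one designated lead, default V2 — the
  lead most sensitive to vertical misplacement. Configurable.
* Landmark amplitudes are read from the normalized beat by default
  (`amplitudes_from_normalized=False` switches to raw mV). A consequence
  worth knowing: the R peak is the maximum of nearly every beat, so
  normalized f4 is ≈ 1 for all beats and the R-attenuation cue migrates
  into the relative features (S/R, onset/offset values, D4, inter-lead
  comparisons). This is why, on this generator, the feature-engineered
  classifiers trail the raw-signal deep networks, which retain the
  amplitude ratio between leads within their normalized inputs.
* Moments use the population (divide-by-n) convention; kurtosis is the raw
  standardized fourth moment (Gaussian → 3).
* The wavelet features use a 4-level DWT, sym4 mother wavelet, symmetric
  (half-point) boundary extension; f12–f14 are the max/min/mean of the
  level-4 detail vector D4 (9.4–18.8 Hz at 300 Hz — QRS-band energy).
  Signals must have at least 112 samples. Approximation coefficients and
  D1–D3 are not used.

## Feature selection

Mutual information is the plug-in estimate on a 10-bin equal-frequency
discretization, in bits; already-discrete columns keep their exact value
partition, so the estimator coincides with direct summation over the joint
table on discrete input. Rankings:

* ENTROPY — univariate information gain, descending;
* MIFS — greedy relevance − β·(summed redundancy), β = 1;
* mRMR — greedy relevance − mean redundancy;
* JMI — greedy sum of joint MI of the candidate paired with each selected
  feature;
* ReliefF — k = 10 nearest hits/misses, all instances, range-scaled
  Manhattan distance.

All ties break toward the lower feature ID. One consequence of the greedy
definitions: a constant column scores exactly 0 under MIFS/mRMR (zero
relevance but also zero redundancy), which can place it above
redundancy-penalized noise features; the purely relevance-driven criteria
(ENTROPY, JMI) rank it last.

Backward elimination walks the ranking from all 16 features down to 1,
dropping the lowest-priority remaining feature each step, and scores every
subset by stratified 10-fold cross-validated accuracy with a fixed seed;
ties go to the smaller subset.

## Classical models

Fine tree (≤100 Gini splits), coarse tree (≤4), bagged trees (30 bootstrap
learners, majority vote), logistic regression, linear SVM and quadratic SVM
(inhomogeneous degree-2 polynomial kernel, coef0 = 1, so the linear terms
are included). Margin/odds models standardize features on the training
fold; trees use raw features; C = 1 throughout. Fits are delegated to
scikit-learn with seeds fixed, so training is deterministic.

## Deep models

Implemented directly in NumPy (forward, backward, Adam) because the
networks are small and single-beat inputs make CPU training cheap; the
engine is single-threaded and bit-reproducible given its seed, and its
analytic gradients are validated against central differences in the test
suite.

* CNN: 15 layers; conv filters 16/32/64 with kernel lengths 16/8/4, "same"
  padding; batch norm (momentum 0.1, eps 1e-5); pool size 2; a 2-unit fully
  connected layer into soft-max.
* BLSTM: 2 bidirectional layers, 64 units per direction by default (the
  pipeline's desk-scale default is 24); the second layer emits the
  concatenation of each direction's final state; forget-gate bias
  initialized to 1.
* Training: Adam at 1e-3, batch 32, up to 100 epochs, early stopping with
  patience 10 on validation accuracy (best weights restored).
* Inputs are the two per-lead-normalized raw signals as 2 channels; the
  deep path never touches the feature vector.

## Evaluation protocol

Splits are by subject (70/15/15 train/val/test, stratified by class): both
placements of a subject stay on one side. This matters: the dataset
contains near-twin rows with opposite labels (the same subject correct and
misplaced), and row-level cross-validation leaks those twins, biasing AUC
systematically *below* chance on zero-effect cohorts. Classical models
train on train+val; the deep models use val for early stopping; every
model is scored on the same test subjects.

The positive class is *correct placement* (label 1), with a flag to invert.
Confidence intervals are Wald with z = 1.96, clipped to [0, 1]; metric
cells with a zero denominator are reported as null with a reason, never
as 0. Desk-scale runs (`RunConfig`) default to 50 subjects per class,
25 epochs and 24 BLSTM units — sizes chosen so a full two-condition,
eight-model run completes in about two minutes on one CPU.

## Known limitations

* Synthetic evidence only: the effect sizes, noise and class morphologies
  are stylized; no claim transfers to clinical data without retraining and
  prospective evaluation.
* The delineator assumes one PQRS cycle with a dominant R deflection; it
  does not handle multi-beat strips, T waves, or QS/rS-dominant morphologies
  where the global extremum is not the R peak.
* MI-based rankings depend on the binning resolution (10 bins) at small n.
* The wrapper respects the filter ordering (drops the lowest-ranked
  remaining feature) rather than re-evaluating all single-feature removals
  per step — the cheaper and deterministic reading of backward elimination
  over ranked features.
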