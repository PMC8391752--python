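# Methods

`fldpred` implements a fatty-liver-disease (FLD) prediction pipeline for
longitudinal health-checkup data: current-visit prediction (CVP) from a
single checkup's features, and next-visit prediction (NVP) from a
subject's irregular visit history. Because the screening dataset this
kind of analysis is run on is proprietary, the package ships a synthetic
cohort generator with known ground truth; every downstream stage is
developed and tested against it.

## Synthetic cohort model

Each subject has a gender, a birth year, and a planned number of visits
drawn from a bounded integer distribution (default 1–8 visits, mean 3.5;
single-visit subjects are kept — they are valid for CVP and excluded
from NVP). Inter-visit intervals are bounded positive integers in months
(default 3–24, mean 12); first visits fall in 2009–2012, so follow-up
extends several years past the recruitment window.

**Latent adiposity.** A per-subject latent trajectory a(t) follows a
stationary mean-reverting AR(1) (discretized Ornstein–Uhlenbeck)
process: between visits separated by Δ years, a_t = φ a_{t−1} +
√(1−φ²) ξ with φ = r^Δ and 1-year autocorrelation r = 0.98. A
mean-reverting process was chosen over a random walk because adiposity
drifts around a personal set point rather than diverging; a random walk
also makes consecutive labels nearly deterministic at realistic
intervals, which would leave the persistence baseline unbeatable and the
marginal label distribution non-stationary across calendar years.

**Features.** The five informative features (named after the
adiposity-related measurements they emulate: BMI, body fat, waist,
triglyceride, fasting glucose) load on a(t) plus independent Gaussian
noise (sd 0.5). Noise features are independent standard normals (15
numeric) and uniform integer levels (10 questionnaire features, 4
levels). Missingness is missing-completely-at-random per feature —
the simplest mechanism consistent with mean/mode imputation — with a
default profile of 5% on informative features, 10% on noise features,
and two numeric noise features at 95% to exercise the
high-missingness drop rule.

**Labels.** The per-visit FLD propensity is a logistic link
p_t = σ(b0_g + Σ_j β_j x_jt) with default effect sizes
β = (1.0, 0.9, 0.8, 0.7, 0.6) and a gender intercept b0_g. Labels form
a chain: each visit draws fresh from p_t, and an explicit persistence
term copies (or, if needed, inverts) the previous label with a global
mixing probability. Two statistics are calibrated jointly by
common-random-number fixed-point iteration (12 passes; the chain is
redrawn with the same uniforms while the parameters move):

* the gender intercepts, so the realized NFLD/FLD class-size ratios hit
  the targets (defaults 0.66 for males, 2.02 for females, i.e. FLD
  prevalence 0.60 and 0.33) for the generated cohort itself, not just in
  expectation;
* the mixing probability, so the realized consecutive-label agreement
  hits `label_persistence` (default 0.8). Persistence 1 freezes every
  subject's label; values far below the chain's natural agreement are
  reached by inverting mixing, at the cost of feature predictability.

This construction deliberately leaves the label *disagreements*
partially predictable from the features: a calibration that forces
P(next = previous | history) to equal the persistence rate for every
single transition would make the previous label a sufficient statistic
and put the persistence baseline at the Bayes optimum — no sequence
model could beat it. Here the agreement is calibrated marginally, so a
model that reads the measurements can out-predict pure label carry-over.

Optional knobs inject structure used by specific experiments: an age
threshold that attenuates the feature–label link (menopause/andropause
analyses) and a calendar year before which the link's sign is flipped
(distribution-shift experiments for the training-window sweep).

**What the generator does not emulate.** Real screening data have
hundreds of correlated features, informative (non-MCAR) missingness,
calendar-time drift in measurement protocols, and visit timing that
depends on health status. Passing tests on this cohort demonstrates
that the pipeline's machinery is correct and that its statistics are
calibrated — not that the reported accuracies transfer to real data.

## Preprocessing

Canonical order: drop configured feature names → drop features with a
missing fraction **at or above** the threshold (default 0.9) → impute →
consolidate questionnaire items → z-score. Z-scoring before imputation
is rejected by contract.

* Imputation: column mean for numeric features, column mode for
  questionnaire features; mode ties go to the smallest level
  (deterministic). Observed values are never altered; an entirely
  missing column is an error.
* Consolidation: each rule derives one numeric feature as a gated
  weighted product of its source items (e.g. a drink-or-not indicator
  gating amount × density × type weight into grams of alcohol; exercise
  frequency × duration × intensity into weekly MET-hours). Coefficients
  are configuration with shipped defaults; the mechanism (many items →
  one numeric feature) is what downstream stages rely on.
* Normalization: (x − x̄)/S with x̄ and S (sample sd, ddof 1) computed
  from a designated fitting subset only — training-only by default, so
  held-out rows never leak into the scaler; constant features map to 0
  with a warning; the statistics are stored on the table.

## Wrapper feature selection

One-pass ranking (OPR) scores every feature **individually**: the
evaluation accuracy of the classifier trained on that feature alone;
features are ranked by score (descending, ties broken by schema order)
and the top-k taken (default k = 24, the expert-list size). Sequential
forward selection (SFS) greedily adds the accuracy-maximizing feature,
re-evaluating at every candidate step. Costs are exactly F evaluations
for OPR and Σ_{i<k}(F−i) for SFS, asserted in tests. Evaluation schemes:
leave-one-out (with an exact fast path for k-NN that queries k+1
neighbors and discards the query point), stratified k-fold, or a fixed
holdout.

The default wrapper classifier is 1-nearest-neighbor, the classic
LOO-wrapper pairing; the neighbor count is a knob. The planted-recovery
experiments use k = 9 neighbors: LOO accuracy of 1-NN on a *single*
continuous feature is an extremely high-variance score, and a smoother
neighborhood makes the single-feature ranking stable without changing
the semantics.

Expert agreement uses IoU(S1,S2) = |S1∩S2|/|S1∪S2| and
coverage(S1,S2) = |S1∩S2|/|S1| against the expert feature list (for
synthetic cohorts, the planted informative features).

## Current-visit prediction

Eight classifiers behind one harness (k-NN, AdaBoost, SVM, logistic
regression, random forest, Gaussian naive Bayes, and entropy- and
Gini-criterion decision trees — the entropy tree stands in for C4.5 on
numeric inputs). Hyperparameters are library defaults with fixed seeds.
AUROC uses predicted class probabilities where available (k-NN vote
fractions included) and a squashed decision function otherwise. Age at
visit is visit year minus birth year. No resampling or rebalancing is
applied anywhere; the imbalance factor (larger class over smaller) is
reported as a diagnostic, and the majority predictor's accuracy equals
the bigger-class fraction by construction.

The training-window sweep evaluates suffix windows ending the year
before the fixed test year; feature selection, when requested, runs
inside the training window only (the test year is firewalled). Best
window = highest accuracy, ties to the longest window. The age-split
analysis partitions visits at each threshold (defaults 53–57 years) and
trains/evaluates independently on each side with Gaussian naive Bayes;
empty or single-class sides are reported as missing.

## Next-visit sequence encodings

Subjects with one visit are discarded. A history of N visits yields
N−1 prefix pairs {v1..vi ⇒ v(i+1)}.

* **Fixed interval (fs1).** The history is resampled to a monthly grid:
  numeric features via shape-preserving piecewise-cubic (monotone
  Hermite) interpolation — chosen over a natural cubic spline to avoid
  clinically absurd overshoots; it degenerates to linear with two
  points — and questionnaire features and the label via linear
  interpolation rounded half-up (a 0.5 label midpoint rounds toward
  FLD), clamped to declared level ranges; visit-month values are
  reproduced exactly. Sliding 12-month windows predict the label 12
  months ahead with stride 1. Default anchors require the full window
  inside the observed span and the target at or before the last visit
  month, so no sample trains on a wholly fabricated target; a
  `pad_left` option instead back-fills the window by duplicating the
  earliest month.
* **Variable interval (fs2).** Each prefix visit is one step of width
  d+2: months since the previous visit (0 on the first step), months
  from the prefix's last visit to the prediction time (constant within
  a sample), then the d feature values. The encoding is lossless for
  visit timing and supports arbitrary horizons by construction.

Splits are 70% train (10% of which validates) / 30% test, stratified on
the target. By default all samples of one subject stay in one split;
window-level splitting of overlapping fs1 samples would leak
near-duplicates across train and test, so subject grouping is the
default and pair-level splitting is opt-in.

## Recurrent classifiers

Five architectures — LSTM, bidirectional LSTM, two-layer stacks of
both, and an additive-attention-pooled LSTM — implemented directly in
numpy with full backpropagation through time, verified against
finite-difference gradients for every architecture. Defaults: 24 hidden
units per direction, Adam (lr 3e-3), batch size 64 with batches
bucketed by sequence length, up to 30–50 epochs. Inputs are
standardized per dimension with statistics fitted on the training
steps (the fs2 timing inputs are on a month scale and would otherwise
saturate the gates); the scaler is stored with the model. The kept
parameters are those of the epoch with the highest validation accuracy
(earliest on ties). Training is deterministic given the seed. The
decision threshold is fixed at 0.5 (a 0.5 score is labelled FLD); no
calibration is applied.

NVP models are trained **per gender** and evaluated pooled, mirroring
the gender-stratified design of screening analyses; this also matters
statistically, because the label link's gender-specific intercepts are
invisible to a pooled feature-only model.

## Baselines and error reduction

Baseline 1 (majority) always predicts the larger training class (ties →
NFLD, with a warning); its test accuracy equals that class's test
fraction. Baseline 2 (persistence) predicts the anchor (previous)
visit's label; its accuracy equals the label-persistence rate of the
test pairs and is the serious baseline a sequence model must beat. The
error reduction rate of a model against a baseline is
(e_b − e_m)/e_b with e = 1 − accuracy; it is 0 when the model matches
the baseline, 1 for a perfect model, and negative when the model is
worse. The formula is validated in tests by an internal-consistency
identity: the baseline error back-solved from one (accuracy, reduction)
pair reproduces the reduction of another pair measured against the same
baseline.

## Problem sizes and numerical choices

Desk-scale defaults keep the full pipeline in minutes on one CPU:
2,000-subject cohorts (≈7,000 visits, ≈5,000 fs2 samples) for
end-to-end runs; 600-subject cohorts for the 20-seed planted-recovery
experiment; 2,300 subjects for the persistence-calibration check
(≥5,000 consecutive pairs). Calibration tolerances: class ratios within
±0.05 of target, persistence and missingness within ±0.02. Degenerate
inputs are handled explicitly: 0/0 IoU is defined as 1 with a warning,
an absent class makes ratio-type diagnostics infinite with a warning,
and a perfect baseline makes the error reduction undefined (error).

## Known limitations

* The recurrent implementation is compact and CPU-oriented; it has no
  dropout, gradient clipping, or learning-rate schedules.
* Grouped splitting satisfies per-stratum fractions only approximately
  (whole subjects move between splits).
* MICE-style model-based imputation is out of scope by design.
* Real-data accuracies from the screening study are not reproduction
  targets; only closed-form worked numbers and calibrated synthetic
  properties are asserted.
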