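# Methods

This note documents the models and procedures implemented in `recuq`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real radiomics data.

## Synthetic cohort generator

The generator (`recuq.synthetic`) emulates a paired pre/post-treatment
PET/CT radiomics study as a purely tabular object:

- **Radiomic features** (107 per series × 4 series by default) are
  marginally standard normal and organized in blocks of 5 consecutive
  features per series sharing a latent factor:
  x = √ρ·f_block + √(1−ρ)·ε, giving every within-block pair correlation ρ
  (default 0.8, deliberately above the 0.7 filter threshold so the
  redundancy filter has real work) and independence across blocks.
- **Clinical covariates** (15) follow a fixed blueprint of mixed types:
  ordinal T stage (1–4), binary smoking/sex/chemotherapy/alcohol/diabetes,
  p16 status as a binary column paired with a missing-indicator column
  (25% missing, missing coded 0), and continuous RT dose (70 ± 4 Gy),
  fractions (33 ± 3), age (60 ± 10 y), BMI, hemoglobin, weight loss and
  follow-up interval. The important-by-default ones mirror the clinical
  factors oncologists associate with recurrence risk.
- **Outcome.** A logistic model on standardized informative columns.
  Default effect vector: 8 radiomic block-leader features at +0.45
  standardized log-odds each (spread round-robin over the four series in
  distinct blocks) and 5 clinical effects (T stage +0.5, smoking +0.4,
  p16 −0.5, RT dose −0.3, fractions −0.3). The intercept is calibrated per
  cohort by root-finding (Brent, tolerance 10⁻⁶) so the mean event
  probability equals the target prevalence, 0.229 by default. With these
  defaults the Monte-Carlo Bayes AUC of the generating logit is ≈ 0.83
  (`oracle_bayes_auc`, n_mc = 2·10⁵), i.e. the planted signal is realistic
  rather than trivially separable.

All randomness flows from the single spec seed through one
`numpy.random.Generator`; identical specs give bit-identical cohorts.

What the generator does **not** emulate: real radiomic marginals (heavy
tails, batch effects), cross-series correlation of the *same* feature,
nonlinear or interaction effects, missingness outside p16, and
measurement error correlated with outcome. Passing tests on these cohorts
therefore establish the *correctness and internal consistency* of the
pipeline, not its clinical performance on real data.

## Nested five-fold design

Folds are stratified by outcome (unstratified folds at 22.9% prevalence
risk one-class validation sets; a `stratify: false` switch restores plain
K-fold). Iteration *i* uses fold *i* for validation and fold (*i*+1) mod 5
for testing, so each fold serves each role exactly once and the pooled
test predictions cover every sample exactly once per seed.

All selection (standardization constants, correlation filter, LASSO path,
candidate scoring, threshold search, model choice) sees only training and
validation data. A config switch `filter_scope: fold|global` exists
because drawing the redundancy filter before the split is a common —
leaky — variant; the default is the leak-free per-fold scope. The test
suite asserts that permuting test-fold labels changes neither the fitted
model nor τ nor the test probabilities.

## Feature selection details

- Z-scoring uses training-fold mean/SD applied unchanged to validation and
  test; zero-variance columns get scale 1 and are removed before the
  correlation filter (r is undefined on constants).
- The greedy filter is deterministic and column-order invariant: the
  currently most-correlated offending pair is processed first; the member
  with the higher mean |r| to all currently retained features is dropped;
  exact ties fall back to canonical (sorted-name) order.
- "LASSO" is L1-penalized logistic regression (liblinear). The penalty
  grid has 50 geometric points from the smallest penalty that zeroes every
  coefficient (max |Xᵀ(y − ȳ)|) down by 10³. Distinct supports of size
  6–10 become candidates; if no support lands in range the closest size is
  used and flagged `size_fallback`.
- Inner scoring uses a linear SVC with sigmoid (Platt-style) probability
  calibration on the training data and the Youden index at the 0.5
  probability cut; the tuned-threshold search is reserved for the outer
  model stage. One-class validation sets yield a NaN score with a flag.
- Ties at selection break toward the smaller support, then the
  lexicographically first name tuple.

## Candidate models and thresholds

Five families: logistic regression (lbfgs, max_iter 5000), linear SVC,
degree-3 polynomial SVC (both with sigmoid calibration, unshuffled
5-fold calibration splits, hence deterministic), a gradient-boosted
additive-tree classifier (scikit-learn `GradientBoostingClassifier`,
library defaults), and XGBoost (logistic objective, library defaults,
fixed seed, single thread). No hyperparameter search by design — the
method's degrees of freedom are in feature selection and thresholding.

The threshold grid is the half-open (0, 0.5] in steps of 0.01: τ = 0 would
predict all-positive, while 0.50 is attainable and occasionally selected.
Ties in the Youden scan resolve to the **largest** τ (favoring specificity
in an imbalanced cohort); ties across model families resolve to the
simplest family in the order LR > SVC > SVCP > GBC > XGB.

## Pooled metrics and grouped importance

Pooled confusion metrics threshold each test record at its own fold's τ;
pooled ROC/PR use raw probabilities (rank statistic with tie correction /
average precision). Single-class subsets keep their confusion metrics and
flag AUC/PRAUC undefined rather than erroring.

The clinical-vs-radiomic importance split uses permutation importance on
the fold's validation data — mean AUC drop over 10 seeded shuffles per
feature, negatives clipped to zero, summed by group and normalized to
100% — because it is model-agnostic across all five families. An all-zero
vector reports 50/50 with a degeneracy flag.

## TTA and off-centered entropy

Noise is drawn independently per sample and per draw, N(0, (0.1·σ_j)²) on
the raw scale of each radiomic feature (σ_j from the training fold);
clinical columns and labels are untouched; k = 5 draws are averaged. A
zero noise scale short-circuits to the exact unperturbed probability, so
the uncertainty layer is provably a no-op at scale 0. No train-time noise
augmentation is applied by default.

The off-centered entropy rescales the probability axis piecewise linearly
so the fold's τ maps to 0.5 — u = p/2τ for p ≤ τ, u = ½ + (p−τ)/(2(1−τ))
otherwise — then applies the standard binary entropy in bits. This form
satisfies the defining properties: e = 0 iff p ∈ {0,1}, e = 1 iff p = τ,
strictly unimodal, and exactly the standard entropy when τ = 0.5.

Exclusion thresholds are empirical quantiles (linear interpolation) of the
fold's validation entropies at the 70/77.5/85/92.5/100th percentiles;
a test sample is excluded when its entropy **strictly** exceeds the
threshold, so ties never over-exclude. The 100th-percentile level (nominal
0% exclusion) retains every test sample by definition, even one whose
entropy exceeds the validation maximum, and reproduces the unfiltered
metrics bit-exactly. On default cohorts (20 seeds, n = 200) mean pooled
accuracy rises monotonically across the sweep — the intended
selective-prediction behaviour.

## Conformal prediction

Class-conditional (Mondrian) inductive conformal prediction with
nonconformity 1 − p(class) and rank p-values
(#{cal scores of class c ≥ s} + 1)/(n_c + 1), ties counted as ≥, no
randomized smoothing (reproducibility over exact-validity smoothing).
Class c enters the prediction set iff its p-value is strictly greater
than α, so empty sets are possible. Calibration probabilities come from
the fold's winning model exactly as fitted in the main pipeline — no
refit on train+validation. Note that the minimum attainable p-value is
1/(n_c + 1): a calibration class with fewer than ⌈1/α⌉ − 1 members can
never be excluded from any set, which at α = 0.05 requires ≥ 19 samples
per class per fold.

Coverage is validated by simulation (50 seeds, 200 calibration / 2,000
test samples, logistic candidate): mean marginal coverage ≈ 95.3% ≥ 95%,
and true-class p-values are super-uniform up to the 1/(n_c+1)
discretization. On the n = 249 pipeline cohorts the certain cohort is
small (tens of samples) and — because the fold winners are weakly
discriminating and imperfectly calibrated at this sample size — not
necessarily more accurate than the uncertain cohort; the
certain-more-accurate ordering is recovered, as theory predicts, when the
probability model is well calibrated (verified in the test suite with the
generator's exact posterior as the model).

## Problem sizes and numerical conventions

Simulation studies use a narrow generator layout (10 radiomic features per
series, 55 columns) and cohorts of 100–600 samples with 10–50 repetition
seeds; these sizes were chosen so each study answers its question with
clear margins while the whole suite stays convenient to iterate on. The
worked analysis uses the full 443-column layout at n = 249 with the five
predefined random states. Sub-seeds for folds, families and shuffles are
derived from the master seed via `numpy.random.SeedSequence`, never from
global state. Frozen reference constants (Bayes-oracle AUC 0.828 for the
narrow spec; reference pipeline AUC 0.735 at n = 600) were computed once
with this package and pinned in the tests.

## Known limitations

- The five candidate families use library defaults; no calibration of the
  boosted models' probabilities is attempted, which directly affects the
  conformal certain/uncertain split at small n (see above).
- The Youden-optimal threshold is itself a noisy statistic on ~50-sample
  validation folds; thresholds near the grid edges (0.01, 0.50) usually
  indicate an unstable fold rather than a real operating point.
- Permutation importance attributes shared signal between correlated
  features arbitrarily; the clinical-vs-radiomic split should be read as
  indicative, not causal.
- The generator's independence between blocks makes the correlation-filter
  task easier than real radiomics, where redundancy is diffuse.
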