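# Methods

This note documents the statistical model behind `greenrad`, the choices
made where the design was genuinely open, and what the synthetic cohorts
do and do not establish.

## Pipeline model and assumptions

The pipeline assumes a samples × features numeric table (no missing
values — rows with missingness are rejected rather than imputed, since
no imputation policy is part of the protocol) and a target that is
either a bounded continuous ratio or a binary label obtained by
thresholding such a ratio. All inference is nested: an outer K-fold
split (default 5 folds for regression, 10 stratified folds for
classification) measures generalisation, and a single 80/20 internal
split of each outer-training portion drives every data-driven choice.
The held-out fold is touched exactly once, by the frozen per-fold
pipeline; pooled out-of-fold predictions cover each sample exactly once.

### Redundancy removal

Pearson `|r|` is computed on the internal training set; pairs strictly
above the threshold (default 0.9) are redundant. Constant features have
undefined correlation; they are flagged, given `|r| = 0` by convention,
and in practice eliminated by the supervised tests (a constant feature
has no discriminative power). The protocol defines only the pairwise
rule, not what to do with correlation *chains* (A~B, B~C, A≁C). We
resolve chains by a greedy sweep in ascending supervised-loss order: a
feature is retained iff no already-retained feature is redundant with
it. This preserves the pairwise rule (every dropped feature has a
retained partner with lower-or-equal loss), yields a pairwise
non-redundant retained set, and is order-independent when losses are
distinct; ties break on column order for determinism.

### Partition losses (DFT/RFT)

Each feature is scored by the best split of its range into two segments:
pooled two-segment RMSE for continuous targets (RFT), sample-weighted
base-2 entropy for binary targets (DFT). The loss is therefore bounded
above by the single-segment value (population SD of the target, or the
entropy of the full label vector), which is also the fallback for
constant features. Candidate thresholds are not prescribed by the
protocol; the default is a uniform grid of 31 interior points over the
feature's training range (`PartitionGrid(n_candidates=31)`), bounding
the cost per feature; an `exhaustive` mode uses midpoints between
consecutive distinct values and is exactly the brute-force optimum (the
test suite verifies this equivalence to 1e-12). `min_segment = 2`
prevents single-sample segments from feigning discriminative power in
cohorts of a few dozen patients. Rankings sort losses ascending, ties
broken by column order. Thresholds on the internal validation set are
searched independently, not transferred from training.

The K elbow points are treated as a hyperparameter grid searched on the
internal validation metric (the protocol's elbows were chosen by visual
inspection, which does not automate); K = 0 means "no raw features":
the booster then consumes only LNT features, and the LNT input is the
entire post-redundancy retained set.

### Least-squares normal transform

Subgroups are strided over the ascending-loss ranking: with `g` groups,
group *i* holds ranks *i, i+g, i+2g, …*, so each group mixes strong and
weak ranks. Where a stride `s` is given without a group count, `s`
groups result (the offset-stride construction yields exactly `s`
groups); when both are given, the group count is authoritative and the
stride used for construction equals it, because the two cannot disagree
under the offset-stride rule.

The solve is the normal equation `A = T Xᵀ (X Xᵀ)⁺` with features
z-scored and the target centred using internal-training statistics. The
bias is fixed at zero: it shifts the derived feature without affecting
its discriminative power, and centring makes the zero-bias solution the
least-squares optimum. In the radiomics regime subgroups are larger than
the sample count, so `X Xᵀ` is singular and the pseudoinverse gives the
minimum-norm solution; a trace-scaled ridge (`1e-8 · tr(XXᵀ)/d`) is the
numerical fallback. Residuals on the fitting data are orthogonal to the
subgroup features (asserted in tests to `1e-8·‖T‖`). Applying a model to
new samples reuses the frozen standardization — no test-fold statistics
enter anywhere.

Note the consequence of the underdetermined solve: on the fitting data
the derived features can interpolate the target even when the target is
pure noise. That is not leakage (held-out folds never touch the fit),
but it makes the internal validation split the only mechanism that can
detect a signal-free fit — which motivates the decision-stage choices
below.

### Decision learning and model selection

The booster is XGBoost (`tree_method="exact"`, single-thread, seeded —
bit-reproducible) constrained to depth ≤ 3 and < 500 trees; both caps
are validated at configuration time. The default hyperparameter grid
crosses depth {1, 3} × trees {50, 300} × learning rate {0.01, 0.1}, and
for regression adds a shrinkage-dominated endpoint (learning rate
0.001, near the intercept-only model). Selection is by internal
validation AUC (classification) or RMSE (regression). Regression applies
a one-standard-error parsimony rule (as in CART pruning or lasso
`lambda.1se`): among candidates within one SE of the best validation
RMSE, the simplest wins. This lets a signal-free fold back off to
near-constant predictions, keeping out-of-fold MSE close to the
mean-predictor baseline under permuted targets. Classification keeps the
plain argmax: AUC is rank-based and scale-free, so near-null candidates
carry no ranking information and a parsimony band only adds selection
noise (measured: it lowered planted-signal AUC by ~0.06 without
improving null behaviour).

### Reported metrics

Regression: MSE/RMSE/MAE pooled and per fold, with mean ± sd across
folds. Classification: AUC as the Mann–Whitney statistic on pooled
out-of-fold scores (ties half-credit) with a 95% DeLong interval
(cross-checked against R's pROC to 1e-9; a stratified bootstrap is
available), a vertically averaged ROC curve on a 0–1 FPR grid of step
0.01, and the confusion matrix of pooled predictions at a probability
threshold of 0.5 (configurable; the protocol does not state an operating
point). Undefined rates (an empty class) are reported as NaN.

A caveat the permutation-null analysis makes explicit: DeLong intervals
assume independent scores, while pooled cross-validation scores are
dependent through shared training samples. Under permuted labels the
pooled null AUC therefore spreads slightly wider than the interval
implies (measured coverage of 0.5 was 8/10 across ten permutation
seeds, with symmetric misses on both sides — the signature of variance,
not leakage, which would elevate AUC one-sidedly).

## The synthetic cohort generator

`CohortSpec` draws features from a single-latent-factor block model:
feature *j* in block *b* is `sqrt(ρ)·f_b + sqrt(1−ρ)·e_j` with `f_b`,
`e_j` independent standard normals, so within-block correlation is
exactly ρ in expectation, cross-block correlation is zero, and
generation costs O(n·d). A latent score `u = w·z + ε` over a sparse
informative subset `z` drives the target through a logistic squash:
continuous targets are `squash_max · sigmoid(u)` (bounded ratios);
binary targets threshold the same construction, with the intercept
calibrated in closed form so the expected positive fraction matches a
requested value (the factor model makes `sd(u)` analytic).

Key parameters and defaults:

- `block_rho = 0.95` in the presets: collapses under `|r| > 0.9`
  filtering the way heavily redundant texture banks do.
- `squash_max = 0.3` for the regression preset (ratio range of the
  emulated expression assay), `1.0` for the binary preset — the ratio
  there must be able to exceed the 0.4 positivity cut-off.
- Presets `pdl1` (52 × 1708, continuous) and `cd68` (78 × 1708, binary,
  expected 22/78 positives at the 0.4 cut-off) reproduce the cohort
  shapes of the emulated study; both use ~670 blocks.
- Preset signal geometry: the 10 informative columns span the first ~4
  correlated blocks rather than 10 independent blocks. With independent
  equal-weight informative features, each feature's correlation with
  the latent score is capped at `1/sqrt(k)` — undetectable per-feature
  at n ≈ 50–80 — whereas real radiomic signal concentrates in a few
  latent tissue properties, each expressed by a correlated feature
  group. The `pdl1` weights keep `sd(u) ≈ 1.6` so the squash stays
  unsaturated and the ratio spreads smoothly below 0.3.
- `planted_spec` (200 × 500, 20 informative features forming two whole
  ρ = 0.95 blocks, weights 2.0) is the strong-signal validation cohort:
  each post-redundancy survivor carries per-feature correlation ≈ 0.7,
  making the signal linearly recoverable by construction. It backs the
  signal-recovery and LNT-discriminativeness checks.

What the generator does **not** emulate: real radiomic feature
distributions (skewness, heavy tails, physical units), nonlinear
feature–biology relationships, scanner/batch effects, or spatial
structure among features. Passing tests on these cohorts establish the
pipeline's *mechanics* — exact losses, leak-free folding, recovery of
linearly recoverable signal — not clinical performance. At the preset
scale (52–78 patients) the pipeline's AUC on simulated cohorts is
modest (~0.6–0.76 depending on seed): an 80/20 internal split of ~60
training samples leaves a ~12-sample validation set, so supervised
selection is noisy. That variability is a property of the protocol at
this cohort size and is reported as measured.

## Numerical choices and degenerate inputs

- Loss ties and ranking ties: broken by column order (determinism).
- Candidate-threshold ties in a partition search: the smallest
  threshold wins.
- Constant features: flagged in the correlation report, `|r| = 0`
  convention, partition-loss fallback to the single-segment value.
- Single-class label vectors: DFT returns loss 0 with a degenerate
  flag; a fold whose stratified split still yields a single class
  raises (the cohort is too small/imbalanced for the fold count).
- Identical seed + configuration ⇒ bit-identical cohorts, reports and
  on-disk artifacts (asserted byte-for-byte in tests).
- `K` larger than the retained dimension is clamped per fold (the
  retained dimension is adaptive); an empty train/validation
  intersection skips that K candidate.

## Problem sizes used in the test suite

Oracle-equivalence checks run on hundreds of ≤50-sample instances;
signal-recovery and permutation-null checks run the full pipeline on
200 × 500 and 78 × 1708 cohorts (seconds per run); the full-scale
smoke test runs one 78 × 1708, 10-fold nested CV. The complete suite
finishes in a few minutes on one CPU.

## Known limitations

- The factor-model cohorts are a stand-in, not a validated emulation of
  radiomic feature distributions (no public cohort exists to fit one).
- DeLong intervals on pooled CV scores are mildly anticonservative (see
  above); fold-aware CV-AUC variance estimators are out of scope.
- The LNT adaptation is the 1-D-target form; multi-dimensional label
  subspaces from the original formulation are not implemented.
- No external-test-set evaluation, calibration analysis, imputation, or
  image/texture feature extraction — the pipeline starts at the feature
  table.
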