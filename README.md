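# greenrad

A Green Learning pipeline for predicting tissue biomarkers from radiomic
feature tables: transparent, feed-forward feature learning for small,
high-dimensional imaging cohorts.

## The problem

Tumor immune microenvironment (TIME) biomarkers — e.g. PD-L1 expression
or the CD68+/PanCK+ tumor-associated-macrophage ratio in clear cell
renal cell carcinoma — are normally measured by multiplex
immunofluorescence on surgically acquired tissue. CT radiomics offers a
non-invasive proxy: a few dozen patients, each described by ~1700
heavily collinear texture features, paired with a bounded ratio target
(regression) or a thresholded positive/negative label (classification).
At that sample-to-feature ratio, end-to-end learned models are opaque
and overfit-prone. This package implements the alternative: a modular,
feed-forward cascade in which every stage is a small, inspectable
statistical operation.

It is written for methods researchers and biostatisticians working with
radiomics-style tables (patients × named numeric features). Because such
cohorts are rarely public, the package ships a first-class synthetic
cohort generator that reproduces the statistical structure the pipeline
assumes — correlated feature blocks, sparse latent signal, bounded-ratio
and imbalanced binary targets — so every stage is testable end to end.

## The method

For a feature matrix with columns `F_j` and target `T`, each outer
cross-validation fold runs the cascade, using only an internal 80/20
split of its training portion for every data-driven choice:

1. **Redundancy removal.** Pearson correlations `r_ij` on the internal
   training set; pairs with `|r_ij| > 0.9` are redundant. A greedy sweep
   in ascending supervised-loss order keeps the better member of every
   redundant pair, so the retained set is pairwise non-redundant.
2. **Supervised feature tests.** Each 1-D feature is scored by its best
   two-segment partition of the dynamic range at a threshold `t`:
   - RFT (regression): `loss = min_t sqrt((SSE_L(t) + SSE_R(t)) / n)`,
     each segment predicted by its own target mean;
   - DFT (classification): `loss = min_t (n_L·H(p_L) + n_R·H(p_R)) / n`,
     `H` the binary Shannon entropy of the segment's labels.
   Lower loss = more discriminative. Features ranked top-K on **both**
   the internal training and internal validation sets form the robust
   intersection set (K = 0 selects no raw features).
3. **Least-squares normal transform (LNT).** The ranked features are
   split into `g` rank-strided subgroups (group *i* takes ranks
   *i*, *i+g*, *i+2g*, …). For each subgroup matrix `X` (features ×
   samples) the normal equation `A = T Xᵀ (X Xᵀ)⁻¹` (pseudoinverse when
   underdetermined; features z-scored, target centred, bias fixed at 0)
   yields one derived "complementary" feature `p = A x` per subgroup.
4. **Decision learning.** XGBoost on the selected raw + complementary
   features, constrained to depth ≤ 3 and < 500 trees; hyperparameters
   and K chosen on the internal validation set.

Out-of-fold predictions are pooled: regression reports MSE/RMSE/MAE
(mean ± sd across folds), classification reports AUC with a 95% DeLong
confidence interval, a vertically averaged ROC curve and the aggregated
confusion matrix.

## Worked example

```bash
python examples/nested_cv_run.py
```

runs the full nested CV on a 200-patient synthetic cohort whose signal
lives in two correlated feature blocks (20 informative features among
500) and prints:

```
pooled out-of-fold AUC: 0.886 (95% DeLong CI [0.834, 0.938])
confusion at 0.5: TP=35 FN=22 TN=131 FP=12
sensitivity 61.4%, specificity 91.6%
booster input dimension across folds: 10-25
  fold 0: 50 retained, K=25, 10 LNT features, depth=1, trees=300
  fold 1: 50 retained, K=0, 10 LNT features, depth=1, trees=300
  fold 2: 50 retained, K=25, 10 LNT features, depth=3, trees=50
```

The AUC is computed purely from held-out folds; "50 retained" is the
dimension left after redundancy removal collapses each correlated block,
and the booster input dimension varies per fold because the
train/validation intersection is adaptive. The other scripts in
`examples/` demonstrate each stage in isolation (simulation, redundancy
filtering, feature screening, LNT generation).

The same pipeline is available as a CLI:

```bash
greenrad simulate --preset cd68 --seed 1 --out cohort/
greenrad run --features cohort/features.csv --targets cohort/targets.csv \
             --task classification --seed 1 --out results/
```

which writes `metrics.json`, `predictions.csv`, `roc_points.csv`,
`selected_features.json` and the resolved `config.yaml`.

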