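# Methods

This note documents the statistical model behind each stage of `convsig`,
the parameters and their defaults, what the synthetic generator does and
does not emulate, and the numerical choices and limitations.

## 1. Extraction pipeline

### Fold partition and extreme responders

Cell lines are randomly permuted (seeded) and dealt into `n_folds = 5`
folds; the analysis for fold *k* retains the lines of the other folds
(80% of the panel), so each fold sees a different resampled screen.
Within retained lines, the `extreme_fraction = 0.2` lowest-IC50 lines are
the *sensitive* group and the highest the *resistant* group
(`floor(fraction · n)` per group; IC50 ties broken by sample id for
determinism). Contrasting extremes rather than regressing on the full
response range sharpens the differential-expression signal at the cost of
discarding the middle of the distribution.

### Differential expression: three tests

All three tests contrast sensitive vs resistant per gene; a gene is a
*seed gene* for the fold when all three call it significantly
**up in sensitive** (log-fold-change ≥ `lfc_cutoff = 0.5` where applicable,
significance cutoff `fdr_cutoff = 0.20`). Requiring agreement of three
methodologically different tests is the convergence idea: each test's
false positives are unlikely to replicate in the other two.

1. **Moderated t.** Empirical-Bayes variance squeezing: per-gene residual
   variances s² with d degrees of freedom are assumed scaled-inverse-chi²
   around a prior (d₀, s₀²). The prior is fitted by method of moments on
   log s² using digamma/trigamma identities (the trigamma inverse solved by
   Newton iteration); the posterior variance is
   s̃² = (d₀s₀² + d·s²)/(d₀ + d) and the moderated t uses s̃ with d₀ + d
   degrees of freedom. Setting `prior_df = 0` recovers the classical pooled
   t exactly (tested to 1e-8); the implementation was verified against the
   standard R reference implementation to 12 digits on a heterogeneous
   -variance fixture. An optional lowess trend (frac = 0.5) lets the prior
   depend on mean expression; the constant prior is the default.
2. **SAM d-statistic.** d = Δmean / (s + s₀) with the fudge factor s₀
   chosen to minimize the coefficient of variation of windowed MADs of d
   over percentiles of s (percentile grid 0,5,…,100; 100 s-quantile
   windows; MAD scaled by 0.64). The null is the permutation distribution
   of d over relabelings: all C(n, n₁) splits are enumerated exhaustively
   when that count does not exceed `n_perm_sam = 10000`, otherwise
   `n_perm_sam` random relabelings are drawn (seeded). Permutation
   statistics are computed by label-matrix multiplications in memory-capped
   chunks. Per-gene q-values follow the standard recipe: for each |d|
   threshold the expected false calls are π₀ · (median permuted calls),
   π₀ estimated by the quartile rule on the permuted d pool; q is the
   running minimum over ascending |d|. Threshold comparisons are nudged by
   `1e-9·|t| + 1e-12` so permutations reproducing the observed statistic up
   to float noise (identity/label-swap splits) count as exceedances —
   without this the exhaustive-enumeration oracle is missed by exactly the
   tied splits.
3. **Westfall–Young minP.** Raw p from the pooled-variance t. The joint
   null is generated by `n_boot_minp = 1000` bootstrap resamples of
   per-gene group-mean-centered data (multinomial-count matrix
   multiplication, chunked); the single-step adjusted p of a gene is the
   proportion of bootstrap minimum p-values at or below its raw p, floored
   at the raw p itself (so adjusted ≥ raw always holds). This controls
   family-wise error and is deliberately the most conservative of the
   three tests.

### Co-expression connectivity

Seed genes should form a coherent program in *clinical* tumors, not just
cell lines. On the clinical cohort (≥ 10 samples required): the affinity of
seed *s* to gene *g* is their Spearman correlation across samples
(average-rank ties; self-pairs are missing). All affinities are pooled and
values strictly above the global `1 − affinity_top_fraction` quantile
(top 5%) become 1, the rest 0. A gene's connectivity score is the mean of
its binarized affinities over the seeds (self excluded). The fold's
*connectivity genes* are the seed genes whose connectivity score lies
strictly above the global `1 − connectivity_top_fraction` (top 20%)
quantile of all genes' scores. Signed (not absolute) affinities are used:
the signature is a positively co-expressed program.

### Consensus

Genes appearing in the connectivity sets of at least
`consensus_min_folds = 3` of the 5 folds form the consensus signature,
ordered by membership count (descending) then lexicographically.

Pipeline defaults (`PipelineConfig`): `n_folds=5`, `extreme_fraction=0.2`,
`lfc_cutoff=0.5`, `fdr_cutoff=0.20`, `n_perm_sam=10000`, `n_boot_minp=1000`,
`affinity_top_fraction=0.05`, `connectivity_top_fraction=0.20`,
`consensus_min_folds=3`, `rng_seed=1`. These are the study conditions; the
seed only affects fold assignment and resampling.

## 2. Scoring and quality control

The signature score of sample *j* is the **median** of the per-gene
z-scored (ddof = 1) expression of the signature genes — robust to a few
off-program genes, unlike the mean. Constant genes are excluded with a
warning; genes absent from the dataset are dropped (or raise, with
`drop_missing=False`). For log-scale display and cross-site comparison,
scores are shifted by `|min| + 1` so a minimum of −5 becomes exactly +1.

QC metrics per dataset: mean pairwise Spearman among signature genes;
Spearman of the mean-z vs median-z summaries and of mean-z vs the first
principal component (SVD, sign-aligned to the mean); score SD; coefficient
of variation of the *shifted* scores (the raw score has mean ≈ 0, making a
raw CV unstable); the fraction of signature genes in the top 10/25/50% of
genome-wide variance; and score skewness. For comparison across candidate
signatures every metric is mapped to [0, 1]: correlations clip at 0,
proportions pass through, SD and CV are min-max scaled across the compared
signatures, skewness maps to `1 − minmax(|skew|)` (less skewed is better —
a choice this package makes; the summary is insensitive to it when
signatures differ mainly in coherence). The *radar area* places the K
metrics at equal angles and divides the shoelace polygon area by the
regular K-gon with unit radii; it is invariant to cyclic rotation of the
metric order but not to permutation — the default order is fixed and
documented (`DEFAULT_METRIC_ORDER`).

## 3. Persistence curves and nulls

With IC50 as "time" and every line an event, the Kaplan–Meier estimator
reduces to 1 − ECDF; it is computed directly that way (machine-exact).
Cohorts (e.g. top vs bottom score quintiles) are compared by the standard
two-group log-rank test and by the hazard ratio of a single-indicator Cox
fit (Efron ties; HR > 1 means the high-score cohort reaches IC50 at lower
concentrations, i.e. is sensitive). With strongly separated cohorts the
indicator approaches complete separation and the HR estimate diverges;
the log-rank p and the null percentile remain well behaved and are the
primary summaries.

The null engine draws `n` random gene sets of the same length (without
replacement, seeded), evaluates any metric on each, drops non-finite
(degenerate) evaluations with a count, and reports the observed
signature's percentile as `100 · #{null < observed}/kept` — strict
inequality, so ties count against the observed signature.

## 4. Prediction suite

Outer 5-fold CV (stratified for the binary outcome); inner 10-fold
`GridSearchCV` on the training fold tunes: elastic net (l1_ratio = 0.5)
/ lasso / ridge over λ ∈ logspace(−3, 2, 15); logistic C ∈
logspace(−2, 3, 15) with saga (elastic net) or liblinear (L1); SVM linear
and polynomial (degree 3–5, γ and C over 1e−3…1e3); random forest with 500
trees. Features are per-gene z-scores with mean/SD fitted on the training
fold only; the 1-D score input is the median of those z-scores. The binary
outcome is IC50 strictly above the included group's median (the median
sample itself is class 0). Continuous models report held-out Spearman rho,
binary models ROC AUC from `predict_proba`/`decision_function`. Each model
reports best/mean/SD across folds; *best-of-folds* is the headline number
by convention of the original analysis and is optimistic — the mean is
reported alongside for honest reading. Degenerate folds (single-class or
constant prediction) yield NaN and are excluded. The quintile variant
restricts to the union of the top and bottom `floor(n/5)` samples by
signature score before splitting.

## 5. Clinical translation

Disease sites with ≥ 25 scored samples are ranked by median shifted score;
rankings from two datasets are compared by Spearman on shared sites (≥ 3
required). Mutation calls are tested against the median score split with
2×2 chi-square (continuity corrected); untestable genes (mutated in none
or all samples) are excluded from the Bonferroni factor.

Risk-model training on the treated arm: genes with expression variance
< 0.2 are removed; a univariate Cox screen keeps genes with coefficient
≤ 0.5 (optionally requiring a negative, protective, coefficient); the
survivors enter one multivariate Cox fit (optional ridge penalizer for
stability). The patient risk score is the linear predictor
η = Σ β_g·x_g. Risk groups come from the median, tertiles, or an
exhaustive cutpoint search: candidate cuts are midpoints of consecutive
sorted unique scores, k ∈ {1, 2} cuts, every group ≥ `min_group = 4`
patients, objective = log-rank chi-square, ties broken toward the lowest
cutpoint(s). The exhaustive search maximizes the statistic and therefore
**inflates the resulting p-value**; treat optimal-cutpoint p-values as
descriptive, and prefer the fixed median/tertile splits for inference.
Groups are compared by Kaplan–Meier curves plus the (multivariate)
log-rank test.

## 6. Synthetic data generator

`SyntheticConfig` defaults: `n_lines=250`, `n_genes=2000`,
`n_program_genes=25`, `program_effect=2.0`, `ic50_noise_sd=0.5`,
`n_blocks=10`, `block_rho=0.3`, `n_clinical=150`, `n_sites=6`,
`site_shift_sd=0.5`, `surv_baseline_hazard=0.03` (per month),
`surv_effect=1.0`, `censor_rate=0.2`, `mutation_rate=0.2`, `seed=1`.

Model: each cell line draws a latent sensitivity u ~ N(0,1);
IC50 = 4.0 − 2.0·u + N(0, `ic50_noise_sd`) on the log2 µM scale (the
intercept and slope place medians in a realistic low-µM range). Program
genes load on u with strength `program_effect` plus unit noise; the
remaining genes form `n_blocks` equicorrelated background blocks
(pairwise correlation `block_rho`) — decoys that are co-expressed but
response-irrelevant. All genes get a baseline of 7 plus per-gene offsets
(log2-microarray-like location), and disease-site mean shifts
(SD `site_shift_sd`). Clinical samples draw their own latent v with the
same program loadings (so the program is co-expressed in the cohort);
treated patients (Bernoulli(½)) have exponential event times with hazard
`surv_baseline_hazard · exp(−surv_effect · score)` where score is the
median program z-score — higher program expression is protective under
treatment; untreated survival is independent of score. Censoring is an
independent Bernoulli(`censor_rate`) with uniform censoring times.
Mutations are Bernoulli(`mutation_rate`) independent of score except one
designated positive-control gene whose mutation probability follows a
sigmoid of the latent sensitivity.

What it does *not* emulate: count-based sequencing noise and
normalization artifacts, batch effects, heavy-tailed or multimodal
expression, realistic linkage between mutations and expression, competing
risks, informative censoring, or dose–response curve fitting (IC50 is
generated directly). Effect sizes are chosen so the planted program is
recoverable at study scale — they are fixed study conditions, not tuned
quantities.

## 7. Numerical choices

- All variances/SDs use ddof = 1; z-scoring raises on constant genes
  rather than producing infinities.
- Quantile cuts for binarization/connectivity use strict `>` on the
  `np.quantile` (linear interpolation) threshold; with heavy ties this
  selects fewer, never more, than the nominal fraction.
- Spearman correlations use average ranks; the affinity matrix is computed
  as a matrix product of normalized centered ranks (identical to pairwise
  `spearmanr` to 1e-12, including ties).
- Permutation/bootstrap nulls are vectorized as matrix multiplications in
  chunks capped by memory, with all randomness from `numpy`'s `default_rng`
  seeded explicitly.
- Survival fits delegate to `lifelines` (Efron ties); persistence curves
  bypass it for exactness. Prediction models delegate to `scikit-learn`.

## 8. Limitations

- Best-of-folds metrics overstate generalization; use the mean/SD columns.
- The exhaustive cutpoint search needs multiplicity-aware interpretation
  (see above).
- minP with 1000 bootstraps cannot resolve adjusted p below 0.001.
- The SAM q-value running-minimum can plateau with very few significant
  genes; the seed-gene intersection with two other tests mitigates
  individual-test artifacts.
- Synthetic validation demonstrates correctness of the machinery, not
  clinical validity of any particular signature on real cohorts.
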