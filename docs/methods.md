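# Methods

## Problem setting

Nerve sheath tumors in neurofibromatosis type 1 (NF1) span four clinical
types — cutaneous neurofibroma (cNF), plexiform neurofibroma (pNF),
neurofibromas without finer subtyping (NF), and malignant peripheral
nerve sheath tumor (MPNST). Cohorts are small, assembled from several
studies (hence batch-confounded with tumor type), and lack matched
normal tissue, which rules out conventional differential expression.
`lvtool` implements an integrative landscape analysis for this setting:
bulk expression is projected into a transferred latent-variable space,
tumor-type-defining latent variables (LVs) are selected with a
resampling ensemble of random forests, and the selected LVs are
characterized through immune deconvolution, regulon (protein-activity)
inference, gene-variant association, and clustering with drug-target
enrichment.

## Latent-variable projection

A PLIER-style model factorizes a reference compendium as `Y ≈ Z B` with
non-negative sparse loadings `Z` (genes × LVs) and an L2 penalty λ₂ on
the scores. Transferring the model to a new cohort is the ridge
projection

    B = (ZᵀZ + λ₂ I)⁻¹ Zᵀ Y′

where `Y′` is the gene-standardized expression restricted to the
model's genes, with genes absent from the cohort imputed at 0 — the
post-standardization mean, the least informative choice. Standardization
uses the sample SD (ddof = 1); zero-variance genes are set to zero and
flagged. The default minimum gene overlap with the model is 0.2 of the
model's genes; below that the projection refuses to run.

LVs whose loading vectors carry nearly the same gene program are
redundant. Deduplication scans LVs in ascending column order and drops
any LV whose loading column has Pearson correlation above the threshold
(default 0.5) with an earlier retained LV. The scan order makes the
procedure deterministic and idempotent; the retained set has no pair
above the threshold.

The most-variable report returns the `ceil(fraction · n_lvs)` LVs
(default fraction 0.05) with the largest across-sample SD, ties to the
earlier LV.

### Batch-effect assessment

Within-study sample distances are compared between gene space and LV
space over the first `n_pcs` (default 2) principal-component scores
(samples as observations, features centered but not scaled). Because
the two spaces have incommensurate scales, each space's distances are
divided by that space's mean over *all* pairwise distances. Under this
normalization, strong batch structure makes between-study distances
large, so the batched space shows *smaller* normalized within-study
distances; the two multisets are compared with a two-sided Wilcoxon
rank-sum test (normal approximation with tie correction — the pair
counts here are large). Studies contributing a single sample are
skipped with a warning.

## Ensemble-of-forests feature selection

Small cohorts make single train/test splits unstable, so performance
and importance are estimated as distributions:

1. stratified 80/20 split into a *model* set and an *independent test*
   set (per class, `round(0.2·n)` test samples, at least one);
2. `mtry` (features per split) and `ntrees` tuned by stratified 5-fold
   CV macro-F1 over a grid (defaults: mtry 1–100, ntrees
   {250, 500, 1000, 2000}); ties prefer the smaller `ntrees`, then the
   smaller `mtry`. For synthetic studies at 200 features the package
   fixes mtry = 14 (≈ √200) and ntrees = 250 instead of re-tuning;
3. 500 (default; synthetic studies scale down to 100 or fewer)
   stratified 75/25 resamples without replacement, each training one
   forest. Per iteration the package records per-class one-vs-rest F1
   on the evaluation split (the iteration's 25% holdout, or the
   independent test set for restricted retraining), Gini importance,
   and per-class permutation importance — the drop in that class's
   recall when one feature is permuted in the evaluation split (one
   permutation per iteration). A resample missing a class is redrawn
   (at most 100 times). Degenerate F1 (no true and no predicted
   positives) is 0 by convention;
4. per class, features are ranked by median importance across
   iterations and the top 40 taken. The selection metric defaults to
   Gini; Gini is class-agnostic, so per-class lists coincide unless the
   permutation metric is chosen — both are always computed and the
   switch is explicit;
5. the union of the per-class lists is retrained as in (3) but
   evaluated on the independent test set, and per-class F1
   distributions (full vs restricted) are compared with Mood's median
   test: a 2×2 chi-square (no continuity correction) of counts above
   vs at-or-below the pooled median, ties grouped below; an all-equal
   pooled sample is reported as p = 1.

Forests are scikit-learn `RandomForestClassifier`s with explicit
`max_features` (mtry), `n_estimators` (ntrees), and a per-iteration
seed derived from the ensemble seed, so the whole procedure is
reproducible bit for bit.

## Immune microenvironment

Two estimators over marker knowledge of immune populations:

* **marker scores** — the arithmetic mean of log2 expression over the
  cell type's marker genes present in the matrix (the MCP-counter
  abundance estimator). Missing markers are logged; a type with no
  marker present is omitted.
* **mixture fractions** — per sample, non-negative least squares of
  linear-scale expression against a genes × cell-types signature
  matrix (log2 input is un-logged as `2^y − 1` first), normalized to
  sum to one (an all-zero fit stays zero), with the unnormalized
  residual RMSE reported. This deterministic constrained-least-squares
  deconvolution replaces ν-SVR-based methods by design: it needs no
  tuning, has an exact-recovery guarantee on noiseless mixtures, and
  feeds only correlation analyses downstream.

Scores are correlated with LV expression (Pearson by default,
Spearman switchable, optionally within tumor types), with BH q-values
across all pairs with a defined correlation; constant vectors are
reported as NA and excluded from the correction.

## Regulon activity

Per sample, genes are rank-transformed, mapped to (0, 1) by
`(rank − 0.5)/n`, and converted to standard-normal quantiles (ties get
average ranks; a constant sample yields a zero signature). For a
regulon with targets `i`, modes `mᵢ ∈ [−1, 1]`, and likelihoods `wᵢ`
(normalized to sum 1), the enrichment score is the weighted, signed
mean `ES = Σ wᵢ mᵢ sᵢ`, and

    NES = ES / sqrt(Σ (wᵢ mᵢ)²)

which has exactly unit variance when signature values are i.i.d.
standard normal. The modes enter the null SD (for ±1 modes this
coincides with the likelihood-only formula); because a real signature
is a permutation of a fixed quantile set, sampling without replacement
makes the analytic null slightly conservative for regulons covering a
large fraction of the genome — negligible at the target-to-genome
ratios used here. This one-tail statistic deliberately simplifies
three-tail VIPER with pleiotropy correction: activity is consumed only
as a correlate of LV expression, where ranking behavior is what
matters.

Multi-network consensus keeps, per (protein, sample), the NES of
largest magnitude across networks containing the protein (magnitude
ties resolve toward the larger signed value, making the rule
independent of network order); a |NES|-weighted mean is available
behind a flag. Activities are related to LVs by Spearman correlation,
with a per-LV count of proteins above a threshold (default 0.65).

## Clustering and drug enrichment

LV rows of the activity-correlation matrix are clustered by
agglomerative hierarchical clustering (Euclidean distance, complete
linkage) and the tree is cut into k groups (default 5) with
`scipy.cluster.hierarchy.cut_tree`, which splits by merge order and is
deterministic even under tied heights. NA correlations are imputed to
0 with a log message. Per cluster, the consensus protein ranking is
the mean correlation of each protein over the cluster's LVs, sorted
descending.

Drug-target enrichment is preranked GSEA: proteins sorted by score
descending, running sum incrementing by normalized |score| (weight
exponent 1) at targets and decrementing uniformly elsewhere; ES is the
signed maximum deviation. The p-value is one-sided for positive
enrichment — the probability under random placement of the target set
(protein-label permutation, default 10,000 draws with a +1/(n+1)
correction; an exhaustive mode enumerates all placements exactly when
feasible). Drugs are BH-corrected jointly; significance requires
ES > 0 and q < 0.05. Target sets covering the whole universe, or with
no target in it, are skipped with a log message.

Cluster expression summaries are the mean of the cluster's LV scores
per sample, joined with tumor type.

## Variant association

For each gene with at least `min_mutated` (default 3; 1 is allowed to
surface single-sample-driven hits) carriers of non-silent variants
(default exclusions: Silent, Intron, 3'UTR, 5'UTR; configurable),
every LV's scores are compared between carriers and non-carrier
*assayed* samples — samples without variant data never enter the
wild-type group. The test is a two-sided Wilcoxon rank-sum, exact when
both groups have ≤ 25 samples and no ties, otherwise the normal
approximation with tie correction; a Welch t-test is available by
config. BH correction runs across all (gene, LV) pairs tested;
direction is the sign of the carrier-minus-wild-type median
difference. Note an intrinsic resolution limit: with 16 assayed
samples split 8/8 the smallest achievable two-sided exact p is
2/C(16,8) ≈ 1.5 × 10⁻⁴, so q < 0.01 across hundreds of LVs is not
attainable regardless of effect size — relevant when choosing
q-thresholds for small cohorts.

## Synthetic data

The generators provide every input with recorded ground truth:

* **loading matrix** — |N(0, 1)| magnitudes masked by
  Bernoulli(sparsity), each LV column guaranteed a nonzero entry;
  matches the non-negative sparse shape of PLIER loadings without
  claiming their pathway structure.
* **cohort** — LV scores are i.i.d. N(0, 1); each class gets
  `planted_per_class` disjoint LVs shifted by `effect_size` (in
  baseline-SD units) in its samples; expression is `Z B` plus
  N(0, noise_sd) gene noise. Batch effects are additive in gene space
  (a per-study N(0, batch_shift²) offset on a random gene subset),
  because that is where batch structure appears in PCA of real multi-
  study cohorts while projection attenuates it. Defaults — effect 3 SD,
  noise 0.5, 10% batch genes — are chosen as a moderately strong,
  recoverable signal regime; the per-class variance structure of real
  LV scores is unknown, so this noise model is a stated stand-in, not
  an estimate.
* **regulons** — targets sampled without replacement, modes ±1,
  likelihoods Uniform(0.5, 1).
* **variants** — each effect gene gets a random carrier subset of the
  assayed samples; the matching LV shift is applied to the score
  matrix by a helper so carrier status and expression stay consistent;
  background variants hit (sample, gene) pairs independently.
* **immune mixtures** — Dirichlet(1) fractions over cell types whose
  markers are expressed at 50:1 contrast over basal; bulk expression
  is the linear mixture, observed through log2(x+1) with 0.1 log2
  units of noise.
* **drug sets** — one planted drug draws its targets from the top
  stratum of the ranked protein universe; the rest are uniform.

Everything is a pure function of its arguments including the seed.
What passing recovery tests on these data shows is that the
implementation detects the structure it claims to detect at realistic
signal-to-noise; it does not show that real tumors contain such
structure, that marker sets are correct, or that the linear mixture
model holds in tissue.

## Numerical and design choices

* Sample SD (ddof = 1) for standardization and variability ranking.
* Pooled-median ties count as "below" in Mood's test (scipy
  `median_test(ties="below", correction=False)`).
* Rounding of stratified split counts is half-up, with a minimum of
  one test sample per class.
* The pipeline fans a single global seed out to per-stage seeds by
  fixed offsets, so stages are independently reproducible; the
  manifest hashes every output file.
* Synthetic study sizes in the test-suite and reproducibility script
  (e.g., 100-iteration ensembles over 200 LVs, 60 samples) are the
  package's chosen desk-scale study conditions; the procedure itself
  has no dependence on those sizes.

## Known limitations

* The deconvolution is not ν-SVR; absolute fraction estimates on real
  mixtures with unmodeled cell types will differ from CIBERSORT-family
  outputs even where correlations agree.
* The one-tail regulon statistic ignores target pleiotropy and shadow
  effects.
* Gini importance is biased toward high-cardinality features in
  general; with continuous LV scores everywhere this is immaterial,
  but the permutation metric is the safer choice when mixing feature
  types.
* The batch-effect statistic tests *relative* within-study compactness
  after per-space normalization; it does not estimate the magnitude of
  batch effects in either space.
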