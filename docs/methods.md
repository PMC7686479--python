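# Methods

This note documents the models, estimators and numerical choices behind
`tprsmap`, and what the synthetic-data generator does and does not emulate.

## Synthetic study generator

The generator (`tprsmap.simulate`) produces every input the analysis chain
consumes, with enough planted structure that each downstream estimator has a
recoverable ground truth.

**Genotypes.** Dosages are built from a blockwise Gaussian copula: for each
of two latent haplotypes, variant j in block B gets
`z = sqrt(r) * F_B + sqrt(1-r) * eps`, with `F_B` a per-subject block factor
and `r = within_block_r`; the allele is 1 when `z < Phi^{-1}(MAF_j)` and the
dosage is the two-haplotype sum. This gives exact binomial marginals at the
drawn MAF and a tunable within-block dosage correlation — the properties the
clumping and relatedness code depend on — without attempting coalescent
realism (no recombination gradients, no allele-frequency spectrum). Blocks
tile chromosomes with 5 kb spacing inside a block and 1 Mb between blocks so
the 250 kb clumping window separates blocks cleanly. INFO scores are drawn
uniform on (0.5, 1], so roughly 40% of variants fail the INFO > 0.80 filter
and QC is exercised at scale; ~5% of variants get strand-ambiguous (A/T,
C/G) allele pairs.

Defaults emulate the target design: 478 subjects in two sex groups, three
task conditions, 76 scored genes. `n_variants` defaults to 3000 because the
uncorrected moment estimator of PIHAT needs on the order of a thousand
post-QC variants before its sampling noise stops producing spurious
exclusions at the 0.2 threshold (at ~350 post-QC variants in LD the
off-diagonal SD is ≈ 0.05 and almost half the sample would be dropped).

**eQTL weights and the planted score.** Each gene receives `snps_per_gene`
distinct variants with N(0, 0.3) weights; a configurable fraction of rows
report the ref allele as effect allele (with the weight negated) so
harmonization is exercised. `simulate_study` mirrors the analysis order —
variant QC first, then imputation and scoring — so the score planted into
the brain data is exactly the score the pipeline recovers; planting a
pre-QC score would attenuate every downstream correlation by the
(irrelevant) overlap between the pre- and post-QC variant panels.

**Brain activation.** Signal voxels are the first `round(signal_fraction *
n_voxels)` voxels in raster order on the grid, which is always one
6-connected block, with a uniform unit-norm salience `s_v = 1/sqrt(m)`.
Each (group, condition) cell contributes
`amplitude * standardized score * s_v` plus N(0, noise_sd²) white noise.
`planted_effects` entries are target **per-voxel correlations** r; the
amplitude is `noise_sd * r * sqrt(m) / sqrt(1 - r²)`, which makes the
realized score–voxel correlation equal r in every signal voxel.
`mediation_a`, when nonzero, instead fixes the amplitude of the designated
mediation cell directly: since the true brainscore (projection onto the
true salience) is `amplitude * z + N(0, noise_sd)`, the amplitude *is* the
raw score→brainscore regression slope a. There is no spatial
autocorrelation, no hemodynamic structure and no between-condition
correlation in the noise; tests passing on these data show the estimators
recover planted linear structure, not that they are robust to realistic
fMRI noise.

**Symptoms.** `anhedonia = mediation_b * brainscore + N(0, noise_sd)`; the
default `mediation_b = 0.1` reproduces a weak brainscore–anhedonia
association (R² ≈ 0.03 at n ≈ 240 per sex), the scale of effect the
emulated design reports. The remaining MASQ subscales and the stress scales
share a configurable correlation (default 0.3, and 0.2 for the stress
scales) with anhedonia through a common factor and carry no brain path.
Scales are continuous Gaussian — no Likert discretization, no floor
effects.

All generator functions are bit-reproducible from `(config, seed)`; every
operation draws from `default_rng([seed, stream_id])` with a fixed stream
id per operation.

## Genotype QC, relatedness and ancestry

QC keeps variants with MAF strictly > 0.01 and INFO strictly > 0.80, drops
A/T and C/G variants and later duplicates of the same
(chromosome, position, allele set); the report accounts for each removal
once, in that order.

PIHAT is the plain method-of-moments IBD estimator from pairwise IBS-state
counts given sample allele frequencies (`P(IBD=1)/2 + P(IBD=2)`), on
hard-called (rounded, mean-imputed) dosages. The small-sample frequency
corrections used by PLINK are deliberately omitted — only the thresholding
behaviour matters downstream — so estimates are clamped to [0, 1] and carry
an O(1/n) upward bias that is negligible at the default panel sizes. For
each pair above the threshold the member with the higher genotype missing
rate is excluded (ties: lexicographically later id); pairs are processed in
decreasing PIHAT order so a subject already excluded resolves its other
pairs.

Ancestry components use classical (Torgerson) MDS of `d = 1 − IBS
proportion`: eigendecomposition of the double-centered squared-distance
matrix, components scaled by sqrt(eigenvalue), variance explained as each
eigenvalue's share of the positive spectrum. A nearest-centroid assignment
against labeled reference subjects in MDS space, with a distance-quantile
cutoff (default 0.95), stands in for reference-panel clustering; the
emulated design does not state its clustering rule, so this is a documented
package choice.

## Scores

Imputed expression is the dosage-by-weight linear combination over
harmonized, matched variants; genes with no matched variant are dropped
with a log message. The T-PRS is `sum_g direction(g) * |weight(g)| *
zscore_g(expression)` with population (ddof = 0) z-scores; z-scoring makes
the score invariant to per-gene affine rescaling, which is the property the
"consistent scale across genes" normalization is meant to provide.
Rank-based inverse-normal transformation is available via
`normalization="rank_inverse_normal"` for heavy-tailed expression. Genes
constant across subjects are dropped (all-constant is an error).

Clumping is greedy: the unassigned variant with the smallest p ≤
`p_index_max` becomes an index (ties: smaller position, then id) and
absorbs unassigned same-chromosome variants within `window_kb` whose
Pearson r² with it (on mean-imputed dosages) reaches `r2_max`. The
threshold PRS averages `beta × dosage` over qualifying index variants so
scores are comparable across thresholds; `score_mode="sum"` gives the plain
sum. An empty threshold yields an all-zero score with a warning rather than
an error.

## Behavioral PLS

`R[cell, voxel]` is the within-group Pearson correlation between score and
activation; zero-variance voxels get 0 with a logged warning, groups under
3 subjects are an error. The SVD uses a deterministic sign convention (the
largest-|entry| of each voxel-salience column is positive).

**Permutation test.** The phrase "resampling the order of conditions" is
operationalized as shuffling the score-to-subject assignment independently
within each group: conditions enter R as rows rather than exchangeable
per-subject labels, and the subject shuffle realizes the null of no
score–brain association while preserving the voxel covariance of each
condition. p-values use the add-one convention
`(1 + #{s_perm ≥ s_obs}) / (1 + n_perm)` per LV, so the smallest attainable
p is 1/(n_perm+1). Under the global null this p is calibrated (the
acceptance suite checks the LV1 rejection rate and KS uniformity over 200
replicate datasets).

**Bootstrap.** Subjects are resampled with replacement within group
(degenerate draws with < 3 distinct subjects or a constant score are
redrawn, with an attempt cap). Each bootstrap SVD is aligned to the
original by orthogonal Procrustes on the behavior saliences — without an
alignment rule the axis/sign indeterminacy of the SVD makes bootstrap SDs
meaningless. Bootstrap ratios are computed on singular-value-scaled voxel
saliences (`v_k s_k`), the convention of the established PLS toolboxes;
scaling matters: on unit saliences the |BSR| > 2.5 rule is markedly
anticonservative under the global null (false-positive rate ≈ 0.10 at
n = 200), while the scaled form sits near 0.03. Behavior-side confidence
intervals are 2.5/97.5 percentiles of the bootstrapped within-cell
correlation between score and brainscore, and may be asymmetric.

**Clusters.** Suprathreshold voxels (|BSR| > 2.5 by default) are
partitioned into connected components on the grid separately for positive
and negative signs, with 6-connectivity by default (the emulated design
does not state a connectivity; 18 and 26 are available), and only
components strictly larger than `min_cluster_size` (default 20) are
reported, sorted by peak |BSR|.

**Brainscores** are condition-wise projections of each subject's voxel
vector onto an LV's unit voxel salience; condition-wise (rather than
concatenated) projection matches the downstream use of per-condition
brainscores.

## Symptom models

Association is plain Pearson correlation with the t-based two-sided p.
Adjusted regression z-scores all continuous variables and reports the
predictor's standardized OLS coefficient (statsmodels OLS); rank-deficient
designs raise an error naming the collinear columns. The Bonferroni gate
for the nine PRS-threshold analyses passes an LV iff its permutation
p < 0.05/9 ≈ 0.0056, strictly.

Mediation fits, per stratum, `a` = OLS slope of mediator on score (+
covariates) and `b` = OLS slope of outcome on mediator adjusting for score
(+ covariates); the indirect effect is `ab`. Uncertainty comes from a
stratified nonparametric bootstrap (default 5000 draws) with percentile
intervals — no bias correction, matching the plain bootstrap-distribution
interval convention; BCa was considered and left out as the default to keep
the interval definition transparent. Moderation by sex is summarized as the
bootstrap difference in `ab` between strata. `standardize=True` (default)
z-scores all variables within stratum so coefficients are standardized
betas; recovery of *raw-scale* planted paths should use
`standardize=False`. Degenerate input note: a fully deterministic chain
(mediator ≡ score) leaves `b` unidentified because the mediator is
collinear with the score in the outcome model; the estimator is validated
in the vanishing-noise limit instead.

## Pipeline

`run_pipeline` executes simulate → qc → ancestry → scores → pls →
associate → mediate from one config. Stage s uses generator seed
`[master_seed, index(s)]`, recorded in the manifest, so any stage re-run in
isolation reproduces its outputs. The manifest stores the config hash and
SHA-256 checksums of every stage output; two runs with identical config and
seed produce identical checksums. Disabling a stage that a later enabled
stage needs fails validation before anything runs, naming the missing
stage.

## Problem sizes and validation scope

The test suite validates estimators against independent oracles
(brute-force loops, eigendecompositions, flood fill, normal equations) on
small fixtures, and calibrates the stochastic machinery by Monte Carlo at
moderate sizes chosen to keep the suite fast: permutation calibration on
200 null datasets (n = 120, 6 cells, 500 voxels, 200 permutations each),
bootstrap-ratio calibration at n = 200 with 500 draws, planted-LV recovery
at 200 subjects per cell with 250 voxels, mediation CI coverage over 100
replicates at n = 500 with 500 bootstrap draws, and sex-specific recovery
over 50 replicates at 250 subjects per stratum.

## Known limitations

- The planted-LV voxel-salience recovery sits at the information limit of
  the SVD estimator at the tested signal strength: with a per-voxel
  correlation of 0.3, 10% signal voxels and 200 subjects per cell, the top
  singular vector's expected alignment with the true salience is ≈ 0.80
  (and is independent of the voxel count, since both the signal singular
  value and the noise operator norm scale with sqrt(voxels)). Stronger
  signals or larger cells are needed for reliable > 0.8 alignment; a
  bagged bootstrap-mean salience estimate was evaluated and does not
  improve alignment.
- PIHAT omits PLINK's small-sample corrections and inherits an O(1/n)
  bias; do not use it for panels under a few hundred variants.
- The permutation unit (subjects within group) is one reading of a
  condition-resampling scheme; a per-subject condition-relabeling null is
  not implemented.
- The generator's noise is white in every dimension; cluster-size
  behaviour under spatially smooth noise will differ.
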