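# Methods

## Model

Observed log2 expression is modeled as

    Y = X β + W α + ε

where `X` encodes the experimental groups (cell-means coding), `β` the
treatment effects of interest, `W` (samples × k) latent unwanted factors
(hybridization day, scanner, lab, platform...), `α` their gene-wise
loadings, and `ε` gene-specific noise. The biology of the design is a
sleep-deprivation pulse followed by recovery: for an affected gene the
true log2 fold change against its time-matched undisturbed control is
`logFC_0` at the end of deprivation (t = 0) and relaxes as

    logFC_t = LA + (logFC_0 − LA) · e^(−t/τd),

with the asymptote `LA` at baseline (0 in the generator) and a class
time constant τd — fast responders discharge in 1–3 h, slow ones by 6 h.
A small "late-induced" class is flat through deprivation and rises only
in the sixth recovery hour.

## Removal of unwanted variation

Two estimators of `W` are provided.

* **negative_controls**: SVD of the sample-centered control-gene
  submatrix; `W` = first k left singular vectors scaled by their singular
  values. Suitable when a trusted list of treatment-insensitive genes
  exists.
* **replicate_samples** (pipeline default): within every replicate group
  the group mean is subtracted, cancelling all biology; the loadings `α`
  are the top k right singular vectors of the stacked differences, and
  each sample's factor activity is recovered by regressing its centered
  control-gene values on `α`. When negative controls are available they
  are used as the control set in this regression: regressing genes that
  respond to treatment would let each group's shared response leak into
  `W` and be removed with it (we observed this shrink late-time logFC by
  ~5% and destabilize τd recovery).

Adjustment is applied either by subtracting `W α̂` or — the pipeline
default — by carrying `W` as covariates in the differential-expression
design. Subtraction necessarily also deletes the component of the true
group profile that happens to lie in span(W) (expected share ≈ k/n
samples, in a random direction per dataset); joint estimation is free of
that bias at a negligible variance cost, so it is the default and the
subtracted matrix remains available for visualization.

**Choice of k.** The k-scan runs adjustment plus differential expression
for k = 0..k_max and recommends the smallest k whose positive-control
recall is within one control gene of the best achieved anywhere in the
scan while the negative-control p-values pass a uniformity check
(KS statistic < 0.1). Recall is evaluated on the SD and RS1 contrasts,
where positive controls are expected to still be differentially
expressed.

## Differential expression

Per-gene OLS on the full group design (optionally + W), residual
variances `s²_g` with `d_g` degrees of freedom shrunk toward a prior by
empirical Bayes: `d0` and `s0²` are obtained by moment matching of
`log s²_g` against the log-chi-square distribution (closed form through
digamma/trigamma inversion; the trigamma inverse by Newton iteration),
and

    s̃²_g = (d0·s0² + d_g·s²_g) / (d0 + d_g),
    t_g = logFC_g / (s̃_g √v_g)  on d0 + d_g df.

Genes with zero residual variance are excluded from the hyperparameter
fit but still tested. `prior_df=0` reproduces the ordinary pooled t
exactly; `prior_df=inf` shrinks every variance to `s0²`. The finite-`d0`
path agrees with the reference R implementation to ~1e-14 on a shared
fixture (a test runs that comparison through Rscript). Multiple testing
uses Benjamini–Hochberg step-up FDR; significance is FDR < 0.01
throughout. The contrasts are the design's time-matched pairs: SD–CC6,
RS1–CC7, RS2–CC8, RS3–CC8, RS6–CC11; time-of-day flags come from
pairwise moderated contrasts among CC0/CC6/CC11.

## Trajectory clustering and τd

Genes significant in at least one contrast are assembled into logFC
trajectories over t = 0, 1, 2, 3, 6 h. Clustering is agglomerative
(Euclidean, complete linkage, deterministic by gene-id order) on
regularized-standardized trajectories: each gene's trajectory is centered
and divided by √(sd² + 0.2²). The floor of 0.2 log2 units — the order of
the logFC estimation noise at 9–10 replicates — matters: dividing by the
raw standard deviation inflates noise-level trajectories into arbitrary
unit-variance patterns that hijack cluster slots, while no scaling at all
groups genes by magnitude rather than kinetic shape. Cluster means and
dispersions are always reported on the raw logFC scale, and
`standardize=False` restores plain Euclidean clustering of raw logFC.

The pipeline excludes time-of-day-flagged genes from clustering (they
are reported separately): the RS3 and RS6 contrasts use controls
sacrificed one ZT hour earlier, so circadian genes carry spurious
late-time logFC that inflates `LA` and biases τd downward.

Classification per cluster: *late_induced* if the majority of member
genes are non-significant at t = 0 but significant at t = 6; else *fast*
if the mean |logFC| at t = 3 has fallen below 25% of its t = 0 value and
the majority of genes are non-significant by t = 3; else *slow*. The 25%
threshold and the majority rule operationalize "recovers within 1–3 h"
and are configuration-exposed.

τd is fitted per cluster on the mean trajectory with `logFC_0` fixed to
the t = 0 mean and `LA` to the minimum of the (oriented) mean trajectory;
clusters recovering upward are negated first so the decreasing form
applies. The single free parameter is found by a coarse geometric grid
over τd ∈ [0.1, 12] h followed by bounded scalar minimization (xatol
1e-10); a trajectory with `logFC_0 = LA` is flagged degenerate. Fixing
`LA` to the observed minimum (rather than 0) makes a pure τ = 1.3 h
cluster fit at ≈ 1.27 h — a small, known bias shared with the procedure
the estimate is compared against. Class-average τd is the unweighted mean
over converged cluster fits; the pipeline drops clusters with fewer than
25 genes from the averages, since complete linkage always emits a few
tiny leftover clusters that are heterogeneous grab-bags rather than
kinetic classes (the threshold sits between the smallest genuine
simulated class, ~40 genes, and the leftovers, ≤ ~25).

## Cross-study integration

Probesets mapping to more than one gene are excluded globally; genes hit
by more than one surviving probeset within a dataset are excluded from
that dataset (both directions of the ambiguity rule). Surviving features
are renamed to gene ids and studies inner-joined, then filtered
(log expression > 4 in strictly more than 50% of samples, both strict)
and quantile-normalized jointly. PCA runs on gene-centered log
expression without unit-variance scaling; each component's scores are
associated to design variables by a one-way variance ratio with the
adjusted-R² level correction, so a fine variable like `replicate_group`
cannot win simply by having many levels.

## Enrichment

EASE p-value: one-sided hypergeometric upper tail on the 2×2 table of
list × term membership inside the background (all dataset genes), with
the overlap count reduced by one (a jackknife that makes single-gene
overlaps never significant and the test conservative overall). Enriched
terms (p < 0.05) are grouped by single linkage on pairwise Cohen's kappa
between their membership vectors over the gene list, at similarity
threshold 0.2 with minimum group size 2; a group's enrichment score is
−log10 of the geometric mean of member p-values and groups ≤ 1.5 stay
out of the headline report. This is a deterministic local replacement
for a web annotation service's fuzzy agglomeration; exact reproduction
of that service's clusters is not attempted, and annotation content is
user-supplied GMT.

## Synthetic data

The generator's defaults are the emulated study's conditions: 96 arrays
in 10 groups (six of 10 and four of 9 samples — the printed group sizes
of 6–7 animals cannot total 96 arrays over ten groups, so the array count
was honored); 10,000 genes; 5% up- and 5% down-regulated with |logFC_0|
uniform on [0.5, 2.0]; τ_fast = 1.3 h and τ_slow = 4.5 h (slow chosen so
recovery completes between 3 and 6 h); 95% of downregulated and 12% of
upregulated transcripts fast, matching the reported class composition;
0.5% late-induced; 10% circadian genes with amplitude uniform on
[0.5, 1.5] log2 and uniform phase, entering as A·cos(2π(zt−φ)/24); k = 3
unwanted factors with i.i.d. standard-normal activities and
normal loadings scaled by batch_strength = 1.0 with a sparse–dense gene
mix (60%/30%/10% of genes at 0.5×/1×/3×); per-gene noise variances
scaled-inverse-chi-square (scale 0.2 log2, 5 df), the same family the
moderated-t prior assumes. Negative controls are drawn from null,
non-circadian genes; positive controls from affected genes above the
60th percentile of the effect-size range, mapped to every contrast.

What the generator does **not** emulate: probe-level intensity effects,
intensity-dependent (trend) variance, correlated gene modules beyond the
shared factors, count noise of RNA-seq, and real annotation structure.
Passing tests therefore demonstrate correctness of the estimators under
the stated factor model, not performance on any particular real dataset.

The multi-study generator adds per-platform and per-lab offset vectors
(sd 2.0 and 1.0 log2 by default, large relative to treatment effects),
per-study factors, per-study probeset dialects with a mapping table,
partial (90%) gene coverage, and planted mapping ambiguities in both
directions.

## Problem sizes and numerical choices

Simulation-based tests run at 1,500–5,000 genes; the repeated-study
checks (τd recovery over 20 studies at the full 10,000 × 96 design, null
FDR over 20 runs) complete in well under two minutes each on a single
CPU. Quantile normalization resolves ties by averaging the tied
reference quantiles. The k-scan's uniformity threshold (KS < 0.1), the
EASE cutoff (0.05), the kappa threshold (0.2), group membership (2) and
the enrichment-score cutoff (1.5) are all configuration-exposed with the
stated defaults.

## Known limitations

* Per-gene (as opposed to per-cluster) τd is not estimated; a cluster's
  τd describes its mean trajectory.
* The replicate-sample RUV variant assumes every condition's replicates
  share unwanted variation with other conditions; a factor perfectly
  confounded with one group is unidentifiable and will not be removed.
* `LA` is held fixed at the trajectory minimum during fitting; jointly
  estimating it would absorb late-time contamination but changes the
  estimator the headline constant is defined by.
* The enrichment stage deliberately does not correct term p-values for
  multiple testing (the conservative jackknife plus the 0.05 cutoff is
  the published operating point).
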