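# Methods

## Statistical model

### Per-gene differential expression

Normalized log2 expression for gene *g* in sample *i* is modeled as

    y_gi = β0 + β_dx · case_i + Σ_k γ_k c_ki + Σ_j δ_j SV_ji + (u_subject) + ε_gi

with known covariates *c* (age, sex, site, brain region for the
repeated-measures design; age, sex, cumulative antipsychotic exposure, brain
pH and post-mortem interval for the shared-control design), surrogate
variables SV, and — for repeated measures only — a subject random intercept
*u* estimated by REML. The reported statistic is Z = β̂_dx / SE(β̂_dx).
p-values are t-based for the fixed model (residual d.f.) and normal-based
for the mixed model; every downstream statistic consumes Z, so this
convention affects only the reported p column. When every subject
contributes one sample the random intercept is not identified and the mixed
fit collapses to OLS exactly (the implementation detects this and takes the
OLS path directly rather than relying on the optimizer at a non-identified
boundary). Mixed fits that fail to converge fall back to OLS on
subject-averaged expression and are flagged.

The OLS path is vectorized: per-gene normal equations are assembled with the
gene's availability mask (X'M_gX, X'M_gy) and solved as one batched inverse
with a determinant-based rank check, so a 1000-permutation ensemble over
thousands of genes with arbitrary per-gene masking is a handful of LAPACK
calls per permutation. Genes with a rank-deficient subsample design or an
(essentially) exact fit are flagged and excluded from cross-disorder
analysis.

### Surrogate variables

SVs are the top right-singular vectors of the gene×sample residual matrix
after regressing each gene on the known design (including the diagnosis
term), refined by one reweighting pass in which each gene is weighted by the
proportion of its residual variance explained by the candidate SVs before a
final decomposition. Columns are orthonormal; the sign convention makes each
SV's largest-magnitude loading positive. Masked entries contribute zero
residual to the decomposition (i.e. they are imputed at the gene residual
mean). SVs are estimated once on the observed labeling and held fixed
across label permutations: permuting diagnosis leaves the SV estimate's
inputs exchangeable given the design, and re-estimating inside each of 1000
permutations would multiply the cost a thousand-fold without changing the
null's validity. `parallel_analysis_n_sv` chooses the SV count as the
number of residual singular values exceeding the 95th percentile of 20
row-permuted decompositions, for designs where no conventional count (the
repeated-measures default is 12) applies.

### Null ensembles

Case–control labels are permuted within strata (collection site for the
multi-site design; unstratified for the single-site shared-control design)
at subject level when subjects contribute multiple samples — all of a
subject's samples receive the subject's permuted label, preserving per-stratum
group sizes exactly. Each of B permutations is refit with the identical
model. Per-permutation seeds derive from the master seed via
`default_rng([seed, b])`, so any permutation can be reproduced in isolation.

### Shared controls and split-control resampling

When SCZ and BPD are compared with each other (directly, or jointly in the
three-way analysis), their shared control arm would otherwise correlate the
two Z vectors. Controls are therefore partitioned at random into disjoint
halves (⌊n/2⌋ / ⌈n/2⌉, assignment uniform per split); one half serves the
SCZ contrast and the other the BPD contrast; the procedure repeats
`n_splits` (default 100) times and each gene keeps its median Z per case
group. Pairwise comparisons against the repeated-measures study (AUT–SCZ,
AUT–BPD) use full-control Z; SCZ–BPD and the three-way comparison use the
split-control medians. Null ensembles for split-control statistics permute
the labels first and then rerun the identical split procedure.

### Cross-disorder products, cutoffs and correlation

The joint statistic is the per-gene product of Z-scores. "Most extreme" is
read as maximum absolute product — the three-way significance rule is
printed with an absolute value, and the same convention is applied pairwise;
sign concordance is reported in its own column so that discordant large
products are visible rather than silently significant. The three-way table
is restricted to genes whose three Z-scores share a sign. The empirical
cutoff at level α is the ⌈(1−α)B⌉-th order statistic of the B
per-permutation maxima of |product| (pairing the b-th permutation of each
ensemble; the three-way null restricts each permutation to the genes
concordant *in that permutation*). A gene is significant iff its |product|
strictly exceeds the cutoff; per-gene empirical p uses the add-one
convention (1 + #{max_b ≥ observed}) / (B + 1), so p ≥ 1/(B+1) and is never
zero. Transcriptome correlation is the Pearson R of two Z vectors over the
common gene universe, with p from pairing the b-th null Z vectors of the
two ensembles and counting |R_b| ≥ |R| (add-one).

The cross-study gene universe is the intersection of the two studies'
post-filter gene sets: products and correlations require both Z's.

### Gene-set enrichment

Per gene, Z-scores from a comparison's disorders combine by Stouffer's
method, Z_comb = (ΣᵢZᵢ)/√k. The set statistic is the absolute set-level
Stouffer value U_S = |Σ_{g∈S} Z_comb,g| / √|S|, computed identically on
every permutation's combined Z; per-set empirical p is add-one, and the
study-wide threshold is the (1−α) quantile of the per-permutation maximum U
over sets. U_S is a deliberate, documented minimal choice: directionally
sensitive, exactly variance-preserving under the null, and consistent with
combining evidence by summation at both the gene and the set level. Sets
with fewer than 5 genes after intersection with the universe are excluded
from all set analyses. Threshold-based DEG lists take genes with |Z| > 2.2
in both disorders (a fixed-size mode takes the top N by min |Z|, ties broken
by gene id) and are tested by upper-tail hypergeometric over-representation
with Benjamini–Hochberg (step-up with monotonicity enforcement) or
Bonferroni correction.

### GWAS overlap

Gene-based GWAS p-values are an input (their computation from SNP summary
statistics is external). Genes with GWAS p below a cutoff (default sweep
0.01, 0.05, 0.1, 1) are selected; the cross-disorder differential expression
p at those genes — the per-gene pointwise empirical p of |Z product| against
its own null ensemble column — is placed on a QQ plot against uniform
quantiles i/(n+1). The same computation on each permutation's p vector
(ranked within the ensemble, minimum 1/B) yields a null band. The visual
judgment is made quantitative through λ = median observed χ²₁ quantile /
median expected: "enriched" iff observed λ exceeds the null ensembles' 95th
percentile. Fewer than 10 selected genes flags the verdict underpowered.

## Preprocessing details

Expression filter: keep gene *g* iff #{samples with count ≥ min_reads} ≥
⌈min_frac · n⌉ (defaults 10 reads, 75%); idempotent by construction.

Normalization: log2 counts-per-million with a library-size-scaled
pseudocount, x = log2((count + 0.5·lib/mean(lib)) / lib · 10⁶). Scaling the
pseudocount by relative library size makes the transform exactly
depth-invariant (samples that are scalar multiples of one another map to
identical values). Each sample's x is then regressed on natural cubic
regression spline bases of GC fraction and log2 gene length (5 functions
each, knots at quantiles); the fitted trend, centered within the sample, is
subtracted. Subtracting only the centered trend preserves per-sample means
and per-gene mean offsets while removing the covariate trends — the spline
span contains linear functions, so a post-hoc linear refit of expression on
GC recovers a slope of zero. This spline-residual scheme stands in for
count-model conditional quantile normalization: the downstream statistics
depend only on trend removal, which this achieves deterministically. A
constant GC or length vector skips that covariate with a warning.

Outlier masking: per gene, entries more than k·s.d. (default 2.7, sample
s.d. with n−1 denominator) from the gene mean are masked, with mean and
s.d. computed once over the gene's current entries — a single pass, never
iterated, and the mask is monotone. A gene with zero s.d. masks nothing.
The n−1 denominator and the single-pass reading are conventions; at the
sample sizes involved the alternatives are immaterial, and one exclusion
step matches a one-shot description better than an iterated trim.

## The synthetic-data generator

Counts are negative binomial (gamma-Poisson) with a single dispersion φ
(variance m + φm², default φ = 0.1): the standard RNA-seq noise model,
sufficient for testing rank and Z behavior. The log2 mean of gene *g* in
sample *i* is

    baseline_g + b_gc(GC_g − mean GC) + b_len(log2 len_g − mean log2 len)
    + covariate effects + site shift + hidden factors + diagnosis·β_g
    + subject intercept (repeated design) + depth_i

with baseline log2 means uniform on (2, 9), GC uniform on (0.3, 0.7),
lengths log-uniform on (200, 20 000) bp, GC slope 2.0 and log-length slope
0.5 (so the normalization stage is consequential), per-sample depth offsets
N(0, 0.2²) log2, per-site gene-level shifts N(0, 0.25²), and hidden factors
loading N(0,1) on a random 30% of genes with sample scores N(0, 1²) — large
enough that surrogate-variable estimation changes results detectably.
Small age and sex effects touch 10% of genes each.

True effects: a common candidate pool of `pool_frac`·n_genes genes (default
20%) receives trivariate-normal log2 effects with marginal s.d. `effect_sd`
(default 0.5) and correlation `rho`; each disorder independently keeps
exactly round(prop_nonnull·n_genes) pool genes non-null (default 10%) and
zeroes the rest, producing both shared and disorder-specific effects with
controllable overlap. Default `rho` uses the transcriptome-level
correlations reported for these disorders (AUT–SCZ 0.298, AUT–BPD 0.06,
SCZ–BPD 0.11). No effect-size distributions are published for the
motivating data, so these defaults are conventions a simulation study in
this field would recognize, fixed once and not tuned.

Study designs mirror the motivating cohorts: a repeated-measures multi-site
design with 40 control and 32 case subjects, each sampled in each of 3
brain regions with probability 0.5 (at least one region, ≈1.5 samples per
subject), subject random intercepts N(0, 0.5²) log2; and a single-region
shared-control design with 31 SCZ, 25 BPD and 26 control subjects. Gene
attributes and baselines derive from the configuration seed so that two
cohorts simulated over the same gene universe share their annotation;
`sample_seed` varies everything sample-level. Generated studies carry their
true hidden-factor scores for validation.

What the generator does **not** emulate: isoform structure, gene–gene
co-expression beyond hidden factors, realistic library-size distributions,
linkage disequilibrium in the GWAS surrogate (null genes are Uniform(0,1),
signal genes Beta(0.1, 1)), or count overdispersion heterogeneity across
genes. Passing tests therefore demonstrate the statistical machinery —
calibration, recovery, invariances — not performance on any real cohort.

## Numerical choices and degenerate inputs

- Empirical p-values everywhere use the add-one convention (1+x)/(B+1).
- A gene whose |product| exactly equals the cutoff is *not* significant
  (strict inequality).
- Control halving for odd control counts: sizes ⌊n/2⌋ and ⌈n/2⌉.
- Rank-deficient per-gene designs (after masking) and exact fits are
  flagged, not silently estimated; genes failing fits are excluded from
  cross-disorder tables.
- Zero-variance Z vectors make the correlation test error rather than
  return NaN.
- All generators and resampling loops are pure functions of (config, seed);
  per-permutation and per-split seeds derive from the master seed.

## Problem sizes used in the test suite

Calibration and power checks run at 2000 genes (9000 where ≈5000 post-filter
products are required), 30 samples per arm, B = 200 permutations, with 200
replicate dataset pairs for family-wise error calibration, 50 for
correlation-p uniformity and 20 for correlation power; split-control
consistency runs the default shared-control design (26 controls) with 100
splits. These sizes give the binomial/KS bands quoted in the tests adequate
resolution while keeping the default suite lightweight on a single CPU.

## Known limitations

- The mixed-model path fits one statsmodels MixedLM per gene; thousand-
  permutation ensembles under the mixed model are computationally heavy and
  should use reduced B or the fixed model on subject-averaged data.
- The set-level statistic U_S is this package's own documented choice; the
  original analysis's set statistic is not fully specified in the available
  description and no claim of equivalence is made.
- Family-wise cutoffs, enrichment thresholds and correlation magnitudes are
  functions of the data analyzed; values computed on synthetic data are not
  comparable to any published cutoff.
- Whether pairwise significance in the motivating analysis used signed or
  absolute products is not distinguishable from its reported results (all
  reported pairwise hits are concordant); absolute is used here, with
  concordance reported separately.
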