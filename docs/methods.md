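# Methods

This document specifies the statistical methods implemented in
`dosagenet`, their default parameters, the synthetic-data model, and the
numerical conventions that make runs bit-reproducible.

## 1. Preprocessing (`dosagenet.preprocess`)

**Filtering.** A gene is retained iff its maximum raw count over all
libraries is ≥ `min_max_count` (default 10). The criterion is idempotent
and order-independent.

**TMM normalization.** Between-library scaling factors follow the
trimmed-mean-of-M-values method. The reference library is the one whose
75th-percentile count fraction is closest to the mean of those fractions.
For each library against the reference, genes with zero counts in either
library are dropped; log-ratios (M) are trimmed by 30 % on each side and
absolute abundances (A) by 5 % (rank-based cuts: the lowest kept rank is
`floor(n·trim) + 1`); the factor is the delta-method weighted mean of the
surviving M values, exponentiated. Factors are rescaled to geometric mean
1. The implementation was verified against the reference R implementation
(`edgeR::calcNormFactors`) to ~4 × 10⁻¹⁵, and that cross-check runs as a
test whenever `Rscript` is available.

**log2 CPM.** `log2((count + 0.5) / (library_size · factor + 1) · 1e6)`
with prior count 0.5.

**Precision weights.** For each gene, the residual standard deviation
around its genotype-wise fitted values is computed; `sqrt(sd)` is
regressed on mean log2 CPM by lowess (span 0.5); the trend, interpolated
at each observation's fitted value and clamped below at the trend floor,
is raised to the power −4 to give an inverse-variance weight (the
mean–variance trend idea behind voom-style precision weights).

**Genotype coefficients.** Per gene and genotype, the weighted mean
`Σ w·y / Σ w` over that genotype's clonal replicate libraries. This is
exactly the weighted-least-squares solution for a one-hot genotype design
(verified against a generalized least-squares oracle), stored as a
genes × genotypes coefficient matrix.

## 2. Relative dosage scores (`dosagenet.dosage`)

Indel events are 1-based inclusive intervals per line, typed `deletion`
or `insertion`. A gene's RDS in a line is 0.5 if a deletion overlaps it,
1.5 if an insertion does, and 1.0 otherwise; a line with both event types
overlapping the same gene is an error. The default overlap policy is
*any* base-pair overlap; a `contained` policy (gene fully inside the
interval) is available.

**Indel normalization** replaces, for every (gene, column) whose line has
RDS ≠ 1.0 at that gene, the expression value with the mean over reference
columns — by default the lines with RDS = 1.0 at that gene
(`non_indel`), optionally all other lines (`all_other`). The operation is
idempotent, drives the expression-on-RDS slope of affected genes to zero,
and emits a replacement log (gene, column, line, RDS, old, new). The
pipeline default is **no** indel normalization; the normalized variant is
one flag away and its differences are fully documented by the log.

## 3. Co-expression network (`dosagenet.network`)

Pearson correlation between genes across samples (constant genes are
dropped with a warning) is soft-thresholded to an adjacency:
`|r|^β` (unsigned, default) or `((1+r)/2)^β` (signed). Default β = 12;
`choose_soft_power` picks the smallest power whose scale-free fit index
reaches the target (default R² ≥ 0.80), where the fit index is the signed
R² of the regression of log10 frequency on log10 connectivity over 10
equal-width connectivity bins.

The topological overlap between genes *i*, *j* is

```
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)
```

with `k` the (diagonal-free) connectivity. Genes are clustered by
average-linkage (UPGMA) on `1 − TOM`; modules come from a **static cut**
of the dendrogram at height 0.99 with minimum module size 30; smaller
clusters are unassigned (`grey`). Modules are named by the conventional
color sequence in decreasing size order (turquoise, blue, brown, …).

A module **eigengene** is the first right singular vector of the
standardized (per-gene z-scored) member matrix, scaled to unit variance
and oriented so the mean correlation with members is ≥ 0. Modules whose
eigengenes correlate at ≥ 0.75 are merged iteratively (largest pair
first, keeping the larger module's name), and eigengenes are recomputed.

**Stability** draws 49 seeded subsamples of 63 % of the libraries,
re-detects modules on each, and reports per-module the median (over
subsamples) of the best Jaccard overlap with any re-detected module.

`CoexpressionNetwork(expression, params).fit()` returns a results object
(labels, eigengenes, dendrogram, optional TOM, scale-free diagnostics,
optional stability) in the estimator/results style of statsmodels.

## 4. Trait integration (`dosagenet.integration`)

Correlations are Pearson; two-sided p-values use the exact
t-transformation `t = r·sqrt((n−2)/(1−r²))` (checked against the
incomplete-beta closed form). Because traits are measured per genotype
while eigengenes live per library, eigengenes are first averaged within
genotype (clonal replicates are not independent observations); module–
trait correlations are then computed over genotypes. Gene significance
(GS) is the correlation of a gene's expression with a trait; module
membership (kME) the correlation with an eigengene. Candidate genes in a
module are ranked by the *worst* of their two ranks on |GS| and kME,
restricted to genes annotated with at least one enriched term.

## 5. Enrichment (`dosagenet.enrichment`)

For module of size *n* with *k* genes carrying a term of background
frequency *K* out of *N*, the p-value is the hypergeometric upper tail
P(X ≥ k) (`hypergeom.sf(k−1, N, K, n)`). The default background is the
annotated genes (`annotated`); `all` uses every labeled gene.
Zero-overlap pairs are not reported. Significance is p < α (default
0.05), uncorrected, as module–term screens are reported per module.

## 6. Dosage-response scan (`dosagenet.dosage_response`)

For a dosage-QTL region, lines are grouped by RDS (deletion / none /
insertion, e.g. 3/4/2 lines); optionally a seeded subset of k control
lines is drawn. For each expressed gene in the region, a one-way ANOVA
across the RDS groups (explicit sums of squares; p from the F survival
function) tests dosage response at α = 0.05; Tukey HSD with
Tukey–Kramer standard errors (studentized-range distribution) yields
pairwise p-values and a compact letter display; the OLS slope of
expression on RDS quantifies the response (noiseless cis genes at γ = 1
have slope exactly log2 3 ≈ 1.585). Degenerate inputs are explicit: zero
within-group variance with non-zero between-group variance warns and
returns F = ∞, p = 0; all-identical data is an error.

## 7. Synthetic data model (`dosagenet.simulate`)

The generator emulates a clonally replicated indel population: default
33 genotypes with 2–3 replicates (91 libraries), 2,000 genes on 19
chromosomes, two dosage-QTL regions (chromosome 9 at 6.3–6.8 Mb with 3
deletion and 2 insertion lines; chromosome 16 at 0–0.5 Mb with 4 and 2),
four planted 50-gene modules, and nine traits with fixed loadings.

* Gene *i* in genotype *g*: `x_ig = b_i + f_{m(i),g} + γ·log2(RDS_ig)`
  with baselines `b_i ~ U(3, 8)` (log2), module factors
  `f ~ N(0, 2.0²)` per genotype, cis effect γ = 1.
* Library counts: gamma–Poisson (negative binomial), mean
  `L_s · 2^x / Σ 2^x`, variance `μ + φμ²`, φ = 0.1, library sizes
  `U(1 M, 3 M)`. Clonal replicates share `x` and differ only by noise
  and depth.
* Traits: `loading · f_{m,g} + N(0, sd²)` per genotype.
* GO map: one construction term per module covering 50 % of members,
  plus random background terms.
* Module genes are drawn outside indel regions so planted trans modules
  stay distinct from cis-dosage genes.

**What it does not emulate:** read-level effects (mapping, GC,
positional bias), isoforms, batch structure, correlated residuals beyond
module factors, dominance/epistasis, partial-overlap dosage (RDS is
three-valued by design), or trait measurement structure beyond additive
Gaussian noise.

Every stochastic stage uses its own `numpy` generator seeded as
`default_rng([seed, stream_id])` with fixed stream ids (annotation 1,
indels 2, counts 3, traits 4), so datasets are byte-identical across
runs and platforms, and changing one stage's draws never perturbs
another's.

## 8. Numerical and reproducibility conventions

* Correlation inputs are made C-contiguous before BLAS calls so summation
  order — and hence the last ulp of dendrogram heights — is stable.
* All closed-form statistics (ANOVA, Pearson p, hypergeometric, Tukey)
  are tested against independent oracles: triple-loop TOM, O(n³) UPGMA
  cophenetic brute force, exhaustive hypergeometric enumeration,
  incomplete-beta p-values, least-squares references, and the reference
  R implementation for TMM.
* Pipeline outputs are written with `float_format="%.10g"`; the run
  manifest records parameters, seed and SHA-256 checksums of every input
  and output, sufficient to verify bit-exact reproduction.

## 9. Modeling decisions on open questions

* **Noise model:** negative binomial via gamma–Poisson mixing; the
  standard count model for RNA-seq overdispersion, and it exposes a
  single interpretable dispersion φ.
* **Tree cut:** the primary pipeline uses the static 0.99 cut; no
  dynamic/hybrid cut is included in scope.
* **Adjacency sign:** unsigned (|r|^β) is the default, matching the
  analysis emulated; signed adjacency is available via a parameter.
* **Stability statistic:** defined here as the median over subsamples of
  each module's best Jaccard overlap with re-detected modules — a
  deterministic, seeded construction chosen because the emulated analysis
  reports only a subsampling proportion (63 %) and count (49).
* **Genotype aggregation:** traits are genotype-level, so library-level
  profiles are averaged within genotype before trait correlation rather
  than pseudo-replicating clones.
* **Indel-normalization reference:** the mean over RDS = 1.0 lines
  (`non_indel`), which zeroes the dosage slope exactly; `all_other` is
  offered for sensitivity analysis.
* **Problem sizes:** tests use 300–2,000 genes and 9–33 genotypes; the
  acceptance recovery run is 2,000 genes × 90 libraries, matching the
  intended scale of a desk-size validation.
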