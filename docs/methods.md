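# Methods

`paraclines` implements the statistical machinery for detecting parallel
latitudinal adaptation of gene expression in two sister species: a
replicated 2 (population: low vs high latitude) × 2 (rearing temperature)
RNA-seq factorial per species, plus pooled per-population allele counts
derived from the same reads. Every stage can be exercised on synthetic
data with known planted truth, which is how the package validates itself.

## The synthetic experiment

The generator (`paraclines.simulate`) is a first-class, tested component.
Its defaults emulate the study design the pipeline models: ~14,000
expressed genes per species on five chromosome arms, ~10,000 one-to-one
orthologs, three replicates per factorial cell, and one pooled sequencing
library per population.

**Genome.** Genes are laid out per arm with random intergenic gaps; each
carries contiguous 5'UTR (100–300 bp), CDS (0.5–2 kb) and 3'UTR
(200–600 bp) intervals, ordered by strand. One arm (3R when present)
receives two contiguous inversion spans covering `inversion_fraction`
(default 0.3) of its genes, standing in for cosmopolitan inversions used
only as genomic intervals in enrichment tests.

**Expression truth.** Each gene gets a baseline log2 mean drawn
N(`baseline_mean_log2` = 7, `baseline_sd_log2` = 1.5). Planted effects add
±`effect_size_log2` (default 1) to specific cells:

- *Differential expression* at a temperature shifts the high-latitude
  mean. A fraction `shared_de_fraction` of ortholog pairs is
  differentiated in both species; each shared pair shares the sign of its
  effect with probability `same_direction_prob`. Additional
  species-specific genes are drawn to reach `de_fraction_per_temp`
  overall. The planted pairs and signs are recorded in the truth object.
- *Plasticity* shifts the warm-reared cells of one population, chosen
  independently per population — so population-specific plasticity also
  produces genuine population differences at the warm temperature, as it
  does in real data.
- *GEI* genes receive a symmetric rank-reversing interaction
  (±e/4 on each of the four cells) giving opposite-sign temperature
  responses in the two populations and a difference-of-differences
  contrast of magnitude e. GEI genes are drawn disjointly from the DE and
  plasticity selections (from non-ortholog genes when enough exist) so
  their planted structure is not overwritten.

**Counts.** Negative binomial with gene-wise shape drawn log-normal
around `dispersion_shape` (default 10, i.e. dispersion φ ≈ 0.1; variance
= μ + μ²/shape), per-sample library factors log-normal (σ = 0.15) and
recorded in the design table.

**Pooled SNPs.** Per gene, Poisson(`snps_per_gene_mean`) SNPs are placed
in its features with class probabilities `annotation_mix`. Each SNP's two
population frequencies are Balding–Nichols draws
Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency
p ~ U(0.1, 0.9), with F = `fst_background_F` (0.05) or, for outlier SNPs,
`fst_outlier_F` (0.5). A SNP is an outlier with probability
`outlier_fraction` (default 0.02), multiplied by
`outlier_in_de_enrichment` when it sits in a differentially expressed
gene's 3'UTR or CDS — this couples genetic and expression differentiation
the way the downstream enrichment tests expect to find it. `outlier_fraction`
is a generator parameter of this package: a base outlier rate is required
for the placement model to be well defined. Read counts are binomial at
Poisson(`pool_coverage_mean`) coverage, one pool per population (the
replicates' reads pooled). Pools are random draws from the population
frequency; within-population line structure of real pooled designs is not
modelled.

**What the generator does not emulate:** read-level error and mapping
bias, isoform structure, linkage disequilibrium between SNPs,
GC/length-dependent count biases, and correlated gene-gene expression
noise. Passing tests demonstrate that the statistics are correct and
calibrated under the stated model, not that the model captures every
feature of real libraries.

All draws descend from a single `seed` through fixed per-stage seed
sequences, so every artifact is bit-reproducible.

## Differential expression

Genes with a mean raw count below 10 across all samples of a species are
dropped (boundary inclusive). Size factors for testing are
median-of-ratios; FPKM reporting uses upper-quartile factors:
FPKM = count · 10⁹ / (length · f_s · L) where f_s is the per-sample 75th
percentile of nonzero counts rescaled to geometric mean 1 and L is the
geometric mean of library totals. This form is exactly invariant to
rescaling any single library, which the more common per-sample-total
variant is not.

The test is a conditional exact test on a negative binomial model:
counts are scaled to a common library size and rounded; under the null the
two group totals are NB with the same per-sample mean, so the split of the
gene's total has a known conditional distribution (a sum of n iid
NB(μ, φ) is NB(nμ, φ/n)). The two-sided p-value sums the probabilities of
all splits at most as likely as the observed one, evaluated in log space
over the region carrying essentially all conditional mass. Dispersion 0
reduces exactly to the conditional binomial (Poisson limit). log2 fold
changes use a pseudocount of 0.5 on normalized group means (configurable).
BH step-up q-values control FDR; NaN p-values propagate without entering
the ranking.

**Dispersion.** Gene-wise method-of-moments estimates
φ̂ = (v − m)/m², pooled across groups and clipped at 0, are shrunk toward
a lowess mean–dispersion trend. The trend weight defaults to
prior_df / (prior_df + residual df) with prior_df = 10 — the
moderated-dispersion convention — giving 0.71 for a 3 vs 3 comparison.
A fixed 50/50 weight was evaluated and rejected: with only 4 residual
degrees of freedom the gene-wise estimates are noisy enough that genes
with underestimated dispersion and accidentally large fold changes
produce anti-conservative far-tail p-values (half of null simulations
yielded BH discoveries). The df-based weight restores calibration in the
package's null-simulation checks. Because the exact test still ignores
residual dispersion uncertainty, mild FDR inflation remains possible at
n = 3; the calibration tests quantify it.

**Gene classes.** Male-biased: male FPKM > 2 and at least 2-fold the
female value. Tissue specificity: tau = Σᵢ(1 − xᵢ/x_max)/(N − 1), 0 for
uniform and 1 for single-tissue expression; testis-biased means tau > 0.9
with maximal expression in testis. Fold-change summaries report the mean
of |fold − 1| in percent (reference population at 1), over all and over
significant genes.

## Cross-species parallelism

All enrichment statistics are the upper-tail hypergeometric probability
P(X ≥ k) for an (N, K, n, k) contingency, computed with scipy's survival
function (log-space internally, stable to ~10⁻³⁰⁰) and cross-checked in
the tests against exhaustive enumeration for every universe N ≤ 25.
One-sided (enrichment) tails are used throughout. The shared-DE overlap
restricts to ortholog pairs expressed in both species; direction
concordance classifies shared pairs by fold-change sign agreement and
tests against 50:50 with a df-1 chi-square, no continuity correction
(pairs with a zero fold change are excluded and counted). The same sign
test applied to all expressed ortholog pairs gives the genome-wide
concordance; Pearson r² of the two species' log2 fold changes among
shared significant pairs measures parallelism of magnitude.

## Plasticity, GEI and reaction norms

Plasticity is DE between temperatures within a population. The
parallelism report computes within-species cross-population sharing with
direction concordance, cross-species sharing per population, and the
cross-species overlap of population-specific (exactly-one-population)
plasticity sets.

The GEI test fits a cell-means linear model per gene on log2(CPM + 0.5)
and tests the contrast (high@Tlow − high@Thigh) − (low@Tlow − low@Thigh)
with a moderated t: residual variances are shrunk toward a scaled
inverse-chi-square prior fitted to all genes by matching moments of
log s² (trigamma inversion by Newton iteration), adding the prior degrees
of freedom to the reference t distribution. A linear model on log-CPM
rather than an NB GLM keeps the variance model simple; calibration is
established by the null simulations.

A gene shows reaction-norm crossover when the sign of the log2
high-minus-low population difference differs between temperatures and
|Δ_Tlow| + |Δ_Thigh| > 0.5 log2 units (threshold configurable; zero cell
means are pseudocounted and flagged). The magnitude rule is one reading of
an ambiguous verbal criterion and is therefore exposed as a parameter.
`slope_discordant` marks genes whose two populations have opposite-signed
temperature slopes.

## Pooled F_ST

Sync-format intake; positions are converted from 1-based to the internal
0-based half-open convention at parse time. SNP filters, in order:
per-pool base coverage < 10 removes the site; a pooled minor-allele count
< 2 removes it; pooled minor-allele frequency < 0.01 removes it; sites
with a third allele at ≥ 2 reads are dropped and counted. The estimator is
the classical heterozygosity form F_ST = (h_T − h̄_S)/h_T with
h = 2p(1 − p), p taken from read frequencies and h_T evaluated at the mean
of the two pool frequencies; it returns 0 when h_T = 0 and is clipped to
[0, 1]. No pool-size/coverage unbiasing is applied, so a small positive
residual remains at F = 0 (order 1/coverage); the tests bound it rather
than hide it.

Tail outliers are flagged per arm: the top ⌊q·n⌋ sites at each quantile
q ∈ {1%, 0.5%, 0.25%}, using a strictly-greater rule against the largest
unflagged value so ties at the threshold are excluded (deterministic, and
avoids tail inflation with discrete values); nesting of the three tails
follows automatically. Annotation assigns each SNP a class by interval
membership with precedence CDS > 3'UTR > 5'UTR when overlapping genes
disagree, recording all host genes.

Enrichment of tail SNPs in DE genes uses as universe the expressed genes
possessing at least one annotated feature of the class. Cross-species
sharing of outlier-bearing genes uses as universe the ortholog pairs with
at least one SNP of the class in both species.

**Matched bootstrap.** To ask whether cross-species sharing of
outlier-bearing genes exceeds what gene size alone produces, each
replicate redraws, per species, a gene set of the observed size in which
every drawn gene has at least as many SNPs as the observed gene it
replaces (processed in descending order, sampled without replacement),
then counts shared ortholog pairs. The empirical p uses the plus-one rule
(1 + #{replicates ≥ observed})/(n_boot + 1) and is never zero. Its null
calibration is checked against a matching null in which a gene becomes an
outlier gene when at least one of its SNPs falls in the tail — the
count-biased process the matching is designed for; against a
uniformly-drawn outlier set the matched null is conservative by design.

## Genome structure

The clustering randomization redraws, per permutation, the observed
per-arm gene counts without replacement and compares (a) the pooled
median start-to-start gap between consecutive selected genes (lower tail:
clustering shrinks gaps) and (b) the number of catalogue-adjacent
selected pairs (upper tail), with plus-one empirical p-values. Arms with
fewer than two selected genes are excluded from the distance statistic
and noted. Per-arm distribution tests are 2×2 chi-squares of DE status ×
arm membership without continuity correction, switching to the exact
hypergeometric (Fisher) form when an expected cell drops below 5, plus a
pooled X-vs-autosome test. Inversion enrichment assigns genes to spans by
midpoint and reports both inside-vs-all-autosomes and
inside-vs-unspanned-autosomes universes. A generic flat term-enrichment
operation (one hypergeometric per term, BH across terms) carries
male-biased/testis-biased/GO-style annotation tests.

## Published-value verification

The headline enrichments of the study this pipeline models are printed as
(N, K, n, k) contingencies with P-values. `verify_printed_statistics`
recomputes each upper tail from the printed counts and compares at the
printed precision, defined as agreement within one unit in the last
printed digit — the printed values are demonstrably truncated rather than
rounded in at least one row, and the one-ulp rule covers both
conventions. Eight of eleven values reproduce. The three failures are
properties of the printed tables, not of the computation: two printed
values equal the point probability P(X = k) instead of the tail (the
tests assert this identity explicitly), and one matches no convention we
could identify. The pipeline reports all eleven recomputed upper-tail
values regardless.

## Numerical choices and problem sizes

- Exact-test support truncation: ±25 conditional standard deviations
  around the conditional mean (always extended to include the observed
  split); omitted mass is far below double-precision relevance.
- Trigamma inversion: Newton iteration, relative tolerance 1e-8.
- Empirical p-values always use the plus-one rule.
- Stage-specific random streams derive from one seed via seed sequences;
  reruns are byte-identical.
- The validation suite runs its simulations at reduced but adequate
  sizes, chosen for statistical power and kept fixed: null-DE calibration
  uses 20 simulations of 1,500 genes; uniformity checks use 100–200
  replicates; parameter recovery uses 10,000 genes; the F_ST enrichment
  power check uses 4,000 genes × 10 SNPs/gene (~40,000 SNPs, the SNP
  count of a full-scale analysis) over 15 replicates; end-to-end
  determinism uses an 800-gene experiment.

## Known limitations

- The exact test treats the shrunk dispersion as known; residual FDR
  inflation at 3 replicates is quantified but not eliminated. A
  quasi-likelihood F-test would propagate that uncertainty.
- The F_ST estimator is intentionally the plain heterozygosity form; it
  is upward-biased at low coverage and not unbiased for pool size.
- Crossover classification from noisy cell means over-calls genes whose
  true population difference is near zero at one temperature; the
  magnitude threshold exists to damp exactly this.
- Ortholog-level analyses assume the one-to-one map is correct; no
  phylogenetic correction for shared ancestry of expression is applied.
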