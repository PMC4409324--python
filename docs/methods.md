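# Methods

## The analysis chain

The package implements the analysis chain used for multi-environment drought
phenotyping of a small, densely genotyped rice diversity panel:

1. plot-level observations → least-squares genotype means per environment;
2. paired control/stress environments → drought-response indices;
3. the genotype × environment cell-mean matrix → AMMI and GGE
   decompositions, sum-of-squares partition, biplot coordinates, dendrograms;
4. cell means per experiment → pairwise-complete Pearson correlation
   structure and significant-partner counts;
5. cell means × binary introgression indicators over 100 kb windows →
   per-window association tests, strict significance filtering, region
   merging and hot-spot co-location;
6. selected regions × QTL annotation sets → one-tailed Fisher's exact
   enrichment.

## Least-squares means

Per environment the additive fixed-effect model `value = μ + genotype_i +
block_j` is fitted by least squares (full dummy design, minimum-norm
solution) and the adjusted genotype mean is the model prediction averaged
over the environment's block levels. Adjusted means are estimable functions,
so the minimum-norm choice does not affect them. For balanced complete
blocks this reduces to the arithmetic genotype mean and coincides with the
mixed-model (random-block) LS means classically used for such trials; the
fixed-effect formulation avoids a REML dependency and is exercised only on
balanced or near-balanced designs. Adding a constant to all plots of one
block shifts every adjusted mean equally: genotype contrasts are invariant,
the absolute level is not (no estimator can hold the level fixed when part
of the data moves).

## AMMI and GGE

AMMI removes μ, G_g and E_e by mean polish (for complete matrices this is
the exact two-way means decomposition) and takes the SVD of the
doubly-centered residual:

    Y_ge = μ + G_g + E_e + Σ_k λ_k α_gk γ_ek + ε_ge.

The SS table is the classical unweighted two-way partition on the cell-mean
matrix (`ss_G + ss_E + ss_GxE = ss_total` exactly for complete data);
`Σ λ_k² = ss_GxE`, and each PC's percentage is `λ_k²/Σλ²·100`.
Replication-count weighting of cells was considered and deliberately not
implemented: the pipeline always consumes LS means, and a single unweighted
definition keeps the partition exactly conservative.

"Location standardized" (GGE) is interpreted as the standard scaling=1
convention: each environment column is centered by its mean and divided by
its sample standard deviation (ddof = 1) before the SVD, making the model
invariant to per-environment affine rescaling. Zero-variance environments
are dropped with a warning.

SVD sign ambiguity is fixed by requiring the largest-magnitude genotype
score on each PC to be positive, which makes all score output deterministic.
The trailing singular value of a doubly-centered matrix is structurally
zero, so min(n_g, n_e) − 1 components are reported.

Missing cells are imputed before decomposition by an EM-style scheme:
initialize from the least-squares *additive* fit on observed cells (exact
for additive data — a naive row/column-mean start can stall on a spurious
fixed point because the centered single-cell indicator is itself rank 1),
then iterate (additive fit + rank-k SVD of the residual), refreshing only
missing cells until the largest change falls below `tol` (default 1e-8,
rank 2 to match the two interpreted PCs, max 500 iterations; non-convergence
returns the last iterate with a warning). Observed cells are never altered.

## Dendrograms

Genotype (or environment) profiles are standardized per feature and
clustered by average linkage on Euclidean distances, computed
pairwise-complete over shared observed cells and rescaled by
`sqrt(m/|shared|)` to the full feature count; pairs sharing fewer than two
cells are an error. Average linkage produces no inversions, so merge heights
are non-decreasing; with continuous data ties have probability zero and the
merge order equals the exhaustive nearest-pair order. Trees serialize to
newick with branch lengths as height differences.

## Correlations

Pairwise-complete Pearson r with two-sided p from the t transform at n − 2
df; pairs with n < 3 or a zero-variance margin are reported missing.
Partner counts use raw p < α (default 0.05) with no multiple-testing
correction — this is a deliberate replication of the published counting
procedure, not an oversight. Listwise deletion was rejected because the
experiments share only subsets of genotypes.

## Introgression-block association

For each 100 kb window the phenotype is regressed on the 0/1 indicator; the
reported statistic is the one-way ANOVA F with 1 numerator df, which equals
the squared pooled-variance two-sample t — the two published formulations
("linear regression", "significance checked by one-way ANOVA") are the same
test for a binary regressor. Windows whose rarer class among phenotyped
genotypes has fewer than 2 members are skipped and counted, never silently
dropped: a 1-vs-19 split is formally computable but fragile. Filtering uses
the strict inequality p < 0.001. Donor groups (aus / indica / japonica) are
scanned as separate tracks.

Significant windows merge into regions only when book-ended (gap = 0),
per (donor group, trait, experiment, chromosome). Hot spots are maximal runs
of contiguous windows whose co-location depth — the number of distinct
(trait, experiment) combinations covering the window — reaches the
threshold (default 5). "Traits aligned" counts (trait, experiment)
combinations, matching how the study colored each contributing experiment
separately. Coordinates are 0-based half-open internally; reports print Mb
with one decimal.

Null calibration is checked by scanning many independent experiments
(fresh phenotype per scan). Within a single scan all windows share one
phenotype vector, so their p-values are mutually dependent and a
conditional uniformity test on one scan would be ill-posed; across
independent scans the p-values are uniform and the p < 0.001 exceedance
rate is binomial.

## QTL-set enrichment

An annotation is the set of 100 kb windows a published QTL intersects; its
enrichment in a region with `n` windows, `k` of them in the annotation's
genome-wide set of `K` windows out of a population of `N`, is the upper tail

    p = P(X ≥ k),  X ~ Hypergeometric(N, K, n),

i.e. the one-sided Fisher's exact test in the enrichment direction (all
reference values correspond to over-representation). The tail is summed in
log space via log-gamma with a suffix log-sum-exp, so p-values far below
float underflow of the individual terms remain exact to ~1e-12 relative;
`P(X ≥ 0) = 1` exactly. The population total is a configuration value
(reference universe: 3680) rather than the union of annotation windows,
because the published universe is fixed independently of the annotation
subset in hand. p-values are formatted in scientific notation at 3
significant figures.

## Synthetic data

The generator reproduces the statistical structure the analyses assume, not
rice biology:

    y_geb = μ + G_g + E_e + Σ_k λ_k α_gk γ_ek + B_eb + ε_geb.

G and E are centered normal draws rescaled so their sums of squares hit the
requested fractions exactly; the interaction is built from random
orthonormal factors orthogonal to the ones vector (exactly double-centered,
hence exactly orthogonal to the main effects), with singular values decaying
geometrically (ratio 0.7 over rank 4 by default); the pooled error vector is
rescaled exactly as well. Requested variance fractions are therefore
realized exactly at the component level, and an independent two-way ANOVA on
the generated table recovers them up to error leakage alone.

Defaults are the study conditions: 20 genotypes, 19 environments (paired
control/stress per site), 3 blocks, grand mean 2500 and total SD 800 on a
kg/ha yield scale, variance fractions {G 0.10, E 0.53, G×E 0.27, error
0.10} — the G:E:G×E ratio of an environment-dominated yield trial
(≈ 11:59:30 among the systematic components) with a 10% plot-error share
added, since published partitions of this kind are computed on cell means.
Block effects (SD 0.25 of total) are absorbed by the LS means.
Missingness is completely at random at the cell level (5%), never reducing
a row or column below two observed cells; whole-genotype removal is an
explicit exclusion list, mirroring photoperiod-sensitive genotypes absent
from some experiments.

Introgression windows are contiguous 100 kb intervals (12 chromosomes × 25
windows by default); each window is assigned at most one donor group with
probabilities {aus 0.05, indica 0.20, japonica 0.50}, mirroring the strong
japonica skew of the reference panel, and carriers are i.i.d.
Bernoulli(0.25). Causal windows add `effect × total SD × (z − z̄)` to the
genotype effects and are guaranteed a donor label. One integer seed feeds
three named sub-streams (phenotypes, blocks, annotations), so each stage is
independently reproducible.

What the synthetic studies do **not** show: real phenotypes have
non-normal errors, spatial field trends, genotype-specific missingness and
linkage disequilibrium between windows; none of these are emulated. Passing
tests demonstrate the correctness of the computations and the calibration of
the tests under the assumed model, not the reproduction of any published
genomic coordinates — the published hot spots, significant-block counts and
region counts require the original panel genotypes and phenotypes and are
out of scope at desk scale.

## Problem sizes and numerical conventions

Simulation-backed tests use 20 genotypes with 6–19 environments and 2–4
blocks, 20 replicates for recovery checks, 10,000 window tests for null
calibration, and an exhaustive oracle sweep of all hypergeometric margins up
to population 60; these sizes keep every check sharp while the whole suite
runs in well under a minute. Tolerances follow the quantity: exact identities
(F = t², SS conservation, reconstruction) at 1e-6–1e-10 relative; stochastic
recoveries at 2–3 percentage points; calibration at 3 binomial SDs and K–S
α = 0.01.
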