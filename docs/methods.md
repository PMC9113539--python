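# Methods

This note documents the statistical machinery, the generative model behind
the synthetic data, the numerical choices, and the known limits of what the
test suite demonstrates.

## Data model

An `OtuTable` is a samples × OTUs matrix (raw integer counts or normalized
real abundances; a `normalized` flag gates operations that are only valid
on one or the other — richness, depth filtering and the Raup–Crick null
refuse normalized input, IndVal refuses raw input unless overridden).
Sample metadata is a data frame keyed by sample id with `elevation`
(meters) mandatory; `pH` must lie in (0, 14) when present; `NA` and empty
cells parse to missing, never zero. Trees are rooted `skbio.TreeNode`
objects with finite non-negative branch lengths; unrooted Newick input is
midpoint-rooted (UniFrac and root-to-tip distances need a root and the
upstream maximum-likelihood inference does not define one; the rooting
choice is recorded in the reader's contract). Geographic distances are
haversine great-circle distances with Earth radius 6,371,008.8 m; the
< 0.5% error against an ellipsoid is negligible at ≤ 3 km site spacing.

## Normalization

Two normalizations are provided. TSS divides each sample by its library
size. CSS (the default) divides each sample by the cumulative count of its
OTUs at or below the sample's median nonzero count (`css_quantile = 0.5`),
then rescales by the median scaling factor across samples; this damps the
leverage a few dominant OTUs exert on between-sample scaling, which
matters for IndVal specificity and abundance-weighted βMNTD. Quantiles use
linear interpolation (type 7) throughout, which is the definition under
which a "first quartile" depth filter threshold is reproducible. Depth
filtering is strictly less-than: a sample exactly at the threshold stays.

## Null models

**βNTI.** βMNTD is abundance-weighted by default (relative abundances
within each sample; unweighted uses 1/richness). The null shuffles taxon
labels across the entire phylogeny — equivalently, jointly permutes rows
and columns of the patristic matrix — and recomputes βMNTD for all pairs
per randomization (999 by default). The same sequence of whole-matrix
permutations serves every pair; per-pair independent null streams would
multiply cost by the number of pairs without changing any per-pair
distribution. βNTI = (obs − null mean)/null s.d. (s.d. with n−1). Pairs
with a degenerate null (s.d. = 0, e.g. symmetric two-taxon configurations)
are reported NaN with a warning and excluded from zone fractions. βNTI is
invariant to rescaling all branch lengths, and on a 4-taxon tree the
Monte-Carlo null matches exhaustive enumeration of all 24 relabelings
(both tested).

**RC-Bray.** Null communities preserve each sample's observed richness S
and library size N: S species are drawn without replacement with
probability proportional to occupancy, receive one individual each, and
the remaining N − S individuals are allocated multinomially in proportion
to regional relative abundance. 999 realizations are generated per sample
and paired across samples (pair r uses realization r of both samples);
this leaves every pair's RC distribution unchanged while reducing the
number of community draws from O(pairs × nulls) to O(samples × nulls).
RC = ((#null < obs) + ½ (#null = obs)) / n_null, rescaled to (RC − ½)·2 ∈
[−1, 1]; ties at half weight, float ties at 1e−12 tolerance. Calibration:
when the "observed" community is itself a draw from this null process, RC
is uniform (≈5% of pairs beyond ±0.95 — tested).

**Classification.** βNTI > +2 → variable selection; < −2 → homogeneous
selection; otherwise RC > +0.95 → dispersal limitation (with drift),
RC < −0.95 → homogenizing dispersal, else drift. Thresholds are
configurable but default to ±2 / ±0.95. Zone boundaries: High strictly
above 1,000 m, Low strictly below 500 m, boundary samples in Middle.

A known property worth stating plainly: deeply sequenced replicate
communities drawn from one shared species pool are *correctly* scored
RC ≈ −1 (they are far more similar than the richness/occupancy null
expects) and hence labeled homogenizing dispersal — which is the
ecologically apt reading of "everything assembles from one common pool".
Drift labels emerge when sampling noise is comparable to the null's
species-identity variance, i.e. at shallow depth and low richness.

## Permutation inference

All permutation p-values use the add-one estimator
(1 + #extreme)/(1 + n_perm), so p ∈ (0, 1]. ANOSIM uses midranks and is
one-sided (9,999 permutations by default); the Mantel family is two-sided
(999 by default) since gradient correlations carry sign. The partial
Mantel statistic is the closed-form partial correlation of the
upper-triangle vectors (equivalently the correlation of residuals after
regressing on the control), permuting the second matrix; an exactly
collinear control raises an error rather than returning an indeterminate
ratio. The Mantel correlogram bins spatial distances into equal-width
classes (Sturges' rule on the pair count by default), negates the
community-vs-membership correlation so that positive values at short
range mean distance decay, and Holm-corrects across classes; classes with
fewer than two pairs report missing statistics. With small discrete label
spaces the permutation tests are conservative (ties inflate p); the
calibration tests therefore use ≥ 12 samples, where rejection at α = 0.05
sits in the 3–7% band.

IndVal follows the specificity × fidelity definition: A_ig = mean
abundance of OTU i in group g over the sum of group means, B_ig = fraction
of g's samples containing i, IndVal = √(A·B), best group by argmax, p by
permuting sample labels against the maximum IndVal. Specificity is not
invariant to per-sample rescaling, so the entry point requires normalized
input by design. Groups default to the singleton elevation zones;
group-combination search is intentionally out of scope.

The bootstrap test of indicator clustering draws, with replacement, *sets*
of distances matching the observed pair count from the community-wide
patristic-distance pool, and compares set-level statistics (mean by
default): a 95% interval for an observed mean requires a sampling
distribution of means, not of single distances. The draw unit and
statistic are configurable.

## Synthetic generator

The generator is the package's test bed and defines its study conditions:

1. **Phylogeny** — pure-birth (Yule) tree, crown start, rate 1.0/time;
   waiting times Exp(k·λ) at k lineages, one extra interval after the last
   split so terminal branches are positive; ultrametric by construction.
   Extinction is omitted: no downstream statistic depends on it.
2. **Optima** — Brownian motion of the elevation optimum along the tree
   (child = parent + N(0, σ²·branch length)), root optimum 800 m, rate
   σ = 200 m per unit branch length½. With tree depths ≈ ln(n), tip optima
   spread over roughly ±400–500 m around the root — spanning the 400–1,200 m
   gradient — and are phylogenetically conserved by construction.
3. **Communities** — regional abundances A_i ~ LogNormal(0, σ_LN); expected
   weight w_is = A_i · exp(−(e_s − opt_i)²/(2σ_f²)); optional dispersal
   mixing replaces each sample's weights with (1−m)·own + m·(group mean)
   *before* the multinomial draw, so library sizes equal the configured
   depth exactly; counts ~ Multinomial(depth, w normalized).

Regimes: `selection` (σ_f = 100 m, m = 0), `neutral` (no filter, m = 0),
`dispersal` (σ_f = 400 m, m = 0.9 with the Low and Middle zones pooled —
downslope mass transport homogenizes the lower mountain — and High mixing
only within itself).

Sampling designs replicate the two published layouts, including each
sample's elevation, pH, temperature and soil organic matter: a 9-station
transect at 400–1,200 m in 100 m steps with 2–3 replicates per station
(24 samples), and 10 single-sample sites at 609–657 m in two watersheds.
Coordinates are synthetic (none are published): the transect runs along a
meridian at ~405 m spacing with fixed perpendicular "trail" offsets so
horizontal and elevation distances are strongly but not perfectly
collinear (mean pairwise horizontal distance ≈ 1,370 m, matching the
reported ~1,361 m); the watershed sites form two 100 m-spaced clusters
~475 m apart (mean ≈ 353 m, matching the reported value).

Per-design sampling scales are anchored to the published per-sample
richness: the transect uses a 150-OTU pool at depth 500
(richness ≈ 43 ± 12, the reported scale being 74 ± 69), the watershed a
40-OTU, strongly dominated pool (LogNormal σ = 2.5) at depth 15
(richness ≈ 7 ± 1.5 against a reported 6 ± 3, consistent with the
reported first-quartile library of 18 reads). The mountain depth is a
compromise: richness variance in the real data is driven by library-size
variation that a fixed-depth multinomial cannot emulate.

What the generator deliberately does not emulate: read-level error, PCR
and primer bias, chimeras, library-size variation, spatial autocorrelation
of soil properties beyond elevation, and taxon interactions. Passing
recovery tests therefore demonstrate that the estimators detect the
processes *as modeled*, not that real soil data are this clean.

## Pipeline & reproducibility

One root seed spawns independent substreams (`numpy` `SeedSequence`) per
stage, so a full run is byte-identical on re-execution and stages run
standalone reproduce the full-run numbers. Every stochastic output records
its seed; the run report validates against a shipped structural schema.
The pipeline stage order is validate → filter → normalize →
alpha/rarefaction → beta (Bray–Curtis, Sørensen partition, UniFrac) →
ANOSIM/Mantel/correlogram → βNTI + RC-Bray → classification and zone
fractions → IndVal → preferred elevation, bootstrap nulls, clade tests,
root-to-tip → report.

## Numerical choices and degenerate inputs

Distance matrices must be symmetric within 1e−10 with zero diagonals
(tiny float asymmetries are symmetrized once, at construction). Bray–Curtis
between two all-zero samples, Sørensen on an empty sample, βMNTD on an
empty sample, IndVal with an empty group, patristic queries on unknown
tips, and Cohen's d with zero pooled variance are all errors, not NaNs.
Rarefaction depths beyond a library report missing. Kruskal–Wallis on
all-tied root-to-tip distances (ultrametric trees) reports p = 1. The
analytic rarefaction expectation uses log-gamma binomials and equals
exhaustive subsample enumeration at small N (tested to N = 12).

## Problem sizes

Default test and acceptance runs use 24–30 samples, 40–150 OTUs and
299–999 null randomizations — sizes at which every null model and
calibration completes in seconds while leaving the Monte-Carlo error well
inside the asserted tolerance bands. All tolerances in the calibration
tests are the bands stated with the corresponding property (95 ± 4% βNTI
coverage, 5 ± 3% RC extremes, 5 ± 2% rejection at α = 0.05).

## Known limitations

* The RC null's species draw is occupancy-weighted only; abundance enters
  through allocation. Other null choices (independent swap, trial swap)
  are out of scope.
* Clade definitions for the clade-divergence test default to maximal
  monophyletic groups of labeled tips; when every tip is labeled this is
  the whole tree, so planned clade sets should be supplied explicitly.
* Conspecific matching between datasets is exact OTU-id matching;
  sequence-identity clustering across datasets is upstream of this
  package.
* Fixed multinomial depth cannot reproduce library-size-driven richness
  variance (see above).
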