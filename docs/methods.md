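# Methods

This note records the models, defaults and design decisions behind
`paramethyl`, and what the synthetic-data validation does and does not
demonstrate.

## Differential methylation

### Model and procedure

Input is a per-cytosine table of methylated/unmethylated call counts
with strand and context (CG, CHG, CHH), 1-based positions.  Counts from
both strands are pooled into contiguous bins of `bin_size` (default
200 bp; 1-based position p maps to bin floor((p−1)/200)), one bin series
per context.  Symmetric CG positions are kept as two cytosines, not
collapsed to dinucleotide units.  Bins and all interval outputs (BED)
are 0-based half-open; conversion happens only at parse/write
boundaries.

A bin enters testing only if, in the default strict mode, *every* sample
in the four-sample comparison has ≥ `min_total` (10) calls in that bin —
this guarantees both chi-square tables are populated.  The alternative
`pooled` mode (sum over samples ≥ 10) is exposed because the coverage
rule could also be read that way; strict is the default because it is
the only reading under which every test statistic is defined.

Each retained bin is tested twice — replicate pair 1 (wt₁ vs sulf₁) and
pair 2 (wt₂ vs sulf₂) — with the Pearson chi-square on the 2×2
methylated/unmethylated table: 1 df, no Yates continuity correction (the
common default for methylation 2×2 tables), p from the χ² survival
function.  Tables with an empty row or column are assigned statistic 0,
p 1.  A bin is a DMR iff max(p₁, p₂) < α (default 0.01).  No
multiple-testing correction is applied: requiring both independent
replicate tests to reject bounds the genome-wide null rate at α² = 10⁻⁴,
and the BED score (−10·log₁₀ max p, capped at 1000) lets users
post-filter.

The methylation difference of a bin is the mean over replicate pairs of
(wt level − sulf level) in percentage points, so negative values mean
hypermethylation in *sulf*.  Direction (hyper/hypo in sulf) is assigned
only when the two pairs agree in sign; significant but discordant bins
are reported separately and excluded from the hyper/hypo tallies, since
a two-way classification is only coherent for concordant calls.

### Region-level test

Regions (e.g. a promoter DMR) are summarised by the weighted level
100·Σmeth/Σtotal per sample; zero coverage yields an explicit no-data
marker (`None`/NaN), never 0%.  Genotype differences are tested with a
binomial GLM (logit link) on the aggregated raw counts — one binomial
observation per sample, genotype as a factor — scored by
likelihood-ratio test against the intercept-only model.  Replicates
enter as independent binomial observations; no replicate covariate is
fitted, because with two replicates per genotype the replicate term
would absorb the residual degrees of freedom.  Statsmodels performs the
fits; tests verify the LRT against a closed-form binomial likelihood
evaluation.  Perfect separation (a group at 0% or 100%) is tolerated:
the deviance difference remains finite and the LRT is still computed.

Sliding-window profiles (default 200-bp windows, 100-bp step, window a
multiple of step) report the weighted level per context per window, with
empty windows flagged as no-data.

## siRNA differential abundance

TMM scaling factors are re-implemented following the canonical
algorithm: reference library = the one whose upper-quartile relative
abundance is closest to the across-library mean; per library, log2
M-values and average abundances A against the reference are doubly
trimmed (30% of M, 5% of A, rank-based with midrank ties) and averaged
with inverse asymptotic-variance precision weights; factors are rescaled
to geometric mean 1.  Factors are computed on the subset of loci present
(count > 0) in every library with row total ≥ 10; if that subset is
empty the factors fall back to 1 (library-size-only scaling) with a
warning.  The implementation is held to ≤10⁻⁶ agreement with edgeR's
`calcNormFactors` and with an independently coded reference in the test
suite.

The genotype test is a Poisson GLM with log link, genotype as an
unordered three-level factor (wt reference), against the intercept-only
model by likelihood-ratio test on (levels − 1) df — an omnibus test, one
p-value per locus.  The default mode follows the original design
literally: the GLM is fitted to TMM-normalised counts rounded to the
nearest integer.  This discards the mean-variance relationship of the
raw counts (normalised counts are not Poisson), which is why an
offset-based mode — raw counts with log effective-size offsets — is
exposed as the statistically preferred alternative; the literal mode
remains the default so results are comparable with the original
analysis.  All-zero loci are reported with p = 1 and a flag rather than
an error.

## Expression classes and candidate triage

The clustering input is a genes × samples matrix of log2
library-normalised values, median-centred per gene (counts are scaled
counts-per-million, log2(x+1)-transformed and centred by
`prepare_matrix`; an already-log2 matrix is only centred).  Distance is
1 − Pearson r across samples; average linkage; the dendrogram is cut so
merges with correlation ≥ r_threshold (default 0.7) stay together.
These are conventional choices — the interactive tool originally used
for this step does not document its exact tree semantics — and are
config-exposed; the validation claims recovery of planted structure, not
equivalence with any particular GUI.  Zero-variance genes are excluded
from the correlation and returned as singleton "flat" clusters.  Genes
are sorted lexicographically first, so the partition is independent of
input order.

Cluster categories come from the sign pattern of the cluster-mean
differences (sulf/+ − wt, sulf − wt), with |difference| < 0.5 log2
(default) counting as unchanged; patterns are I (−,−), II (0,−),
III (+,+), IV (0,+), anything else "other".  The assignment is invariant
to adding a constant to a cluster's samples.

The positional candidate filter intersects: adjusted p < 0.05, log2FC
(wt over sulf) > 0, chromosome match, and gene end ≤ boundary.
"Upstream of the S locus" is fixed as gene end at or before the boundary
coordinate (the pericentromeric side), boundary inclusive; the boundary
is user-supplied configuration, not inferred.  Candidates are ordered by
descending fold-change, so the most repressed gene ranks first.  DE
calling itself is consumed as input (it belongs to the upstream
count-based DE tool), not recomputed.

## qPCR assays

Amplification efficiency defaults to 2.0 (perfect doubling per cycle)
and is configurable per assay; no efficiency calibration is estimated.
"No amplification" is encoded as Cq = +∞, under which the surviving
fraction E^(Cq_u − Cq_d) → 0 and the McrBC proportion → 100% without
special-casing; proportions are clamped to [0, 100] so a digested sample
amplifying earlier than its control reads 0%.  Relative expression uses
the geometric mean of two housekeepers; replicates are averaged on the
Cq scale.  Fold-change comparisons use a Welch two-tailed t-test on log2
abundances by default (the conventional scale for qPCR ratios); a
raw-scale option is provided.

## Synthetic data: what it emulates

The generators reproduce the statistical structure the analysis assumes,
with planted ground truth for recovery tests:

- **Methylome** — cytosine sites as homogeneous Bernoulli processes per
  context and strand (per-strand densities CG 0.02, CHG 0.02,
  CHH 0.10 /bp; collisions resolved CG > CHG > CHH so sites are unique
  per strand); coverage Poisson with mean 5 (the emulated shotgun
  depth), 50 for high-precision estimator checks; methylated calls
  beta-binomial with mean level p and dispersion ρ (ρ = 0, the default,
  is binomial — no stated between-replicate biological variance to
  emulate, so ρ is a knob, not a fitted quantity).  Planted regions
  override the background level per context and genotype.  Two bundled
  region archetypes mirror the promoter DMRs of the motivating system: a
  727-bp region hypermethylated in sulf in all contexts
  (CG 24%→73%, CHG 4%→62%, CHH 0.7%→4%) and an adjacent
  region hypomethylated in the non-CG contexts (CHG 93%→78%,
  CHH 27%→4%); the second region's length is not published, so 600 bp —
  the same scale as the first — is used.  Null-calibration runs use a
  genotype-identical CG-only background at 30%.
- **sRNA** — locus × library Poisson counts, mean = library size ×
  baseline × per-genotype fold-change, over the 2+2+2 library design
  (wt, sulf/+, sulf).  Power scenarios plant effects in 5% of 2000 loci
  (baseline mean 20, 4-fold in sulf, 2-fold in sulf/+): differential
  loci are a small minority, as in real sRNA populations, which is what
  TMM's trimming assumes.
- **Expression** — per-gene log2 values = class pattern (±2 log2 in the
  affected genotypes) + Gaussian noise (sd 0.2) over a 2 wt + 3 sulf/+ +
  3 sulf sample layout.  The generator emits an already-normalised
  matrix, a DE table and a sequential gene annotation with a designated
  S-locus coordinate.  The DE table's adjusted-p proxy is derived from
  the planted truth (exactly 1 for null genes; the two-sided normal tail
  of the planted contrast otherwise) — it stands in for an upstream DE
  caller that is out of scope, and is deliberately noiseless so filter
  tests are exact.
- **qPCR** — small Cq tables with methylated/unmethylated McrBC pairs
  and a strong target knock-down, for end-to-end runs.

What passing these tests does **not** show: robustness to conversion
failure, mapping bias, coverage heterogeneity, or overdispersed
biological replication (all generators are exchangeable and, by default,
at ρ = 0); TMM behaviour under extreme composition bias; cluster
recovery when classes blend continuously.  The validation demonstrates
that the statistics are implemented correctly and behave as designed
under their own assumptions, not that those assumptions hold for any
particular real dataset.

## Problem sizes and numerics

Calibration and recovery runs are sized to give tight binomial intervals
while remaining desk-scale: ~117 000 retained CG bins (24-Mb simulated
chromosome) for the null-rate check; 100 planted 727-bp regions for
sensitivity; 2000 loci for Poisson calibration; 200 genes for clustering
recovery.  Sensitivity is evaluated on bins fully inside a planted
region that pass the coverage filter and carry ≥10 cytosines of the
context, matching the caller's stated operating range; partially
overlapping boundary bins are excluded from both sensitivity and
specificity tallies since their truth is mixed.  Chi-square computations
are vectorised closed-form Pearson; equality with scipy's contingency
test and a brute-force Σ(O−E)²/E is asserted to 10⁻⁸.  GLM fits use
statsmodels defaults (IRLS); likelihood-ratio statistics are clipped at
0 against roundoff.  Seeds derive from a single master seed via
`numpy.random.SeedSequence`, and every generator is deterministic given
its spec and seed.

## Known limitations

- The literal Poisson-on-normalised-counts mode inherits the original
  design's miscalibration risk when normalisation factors stray far from
  1; use the offset mode for new analyses.
- The dual chi-square rule tests bins independently; adjacent-bin
  correlation is ignored and no region merging is performed.
- The clustering cut is a hard threshold on merge correlation; classes
  whose mean patterns correlate above the threshold will merge.
- `run-all` is a linear orchestrator; it does not parallelise or resume.
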