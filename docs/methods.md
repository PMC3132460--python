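# Methods

## Region model and coordinates

All internal coordinates are 0-based half-open (the BED convention);
printed 1-based inclusive coordinates are converted on load, so the gap
printed as 1,423,147–1,478,646 becomes `[1423146, 1478646)` with an
unambiguous length of 55,500 bp. The region is one synthetic coordinate
system labelled by `build_label`; no liftover between assembly builds is
attempted, because no reference genome sequence is consumed anywhere.

The default region spans `[550000, 1850000)` (1.3 Mb). Besides the
probe-free gap, two default LCR no-call masks abut the gap
(`[1395000, 1423146)` and `[1478646, 1505000)`), emulating the low-copy
repeats that cluster around subtelomeric gaps. Masks carry probes but
those probes are never interpreted — segments there are emitted as
`no_call`.

## Synthetic data generator

The generator emulates the statistical structure the callers assume, not
raw two-channel microarray physics (no dye effects, no B-allele
frequencies, no reference-genome sequence).

* **Designs.** Probes are 60-mers tiled at fixed spacing (screening
  5,000 bp, tiling 500 bp by default — actual platform spacings within
  the region are not published, so these are package choices giving ~249
  and ~2,489 probes). Probes overlapping the gap are dropped; probes in
  masks are retained but masked at calling time. GC fraction follows a
  smooth positional wave (0.45 ± 0.08, period 300 kb) plus seeded jitter.
* **Cohort.** Carrier status is Bernoulli per sample with status-specific
  prevalence (defaults 0.13 for 100 cases, 0.01 for 100 controls, the
  studied cohort's rates); `carrier_counts` can instead fix exact counts
  to emulate a printed table. Each carrier receives one CN=1 deletion
  whose length is uniform in [200, 500] kb and which always covers the
  gap (the gap is the rearrangement hotspot the study design targets).
  Homozygous deletions are not simulated: only "loss" versus "unchanged"
  is modelled.
* **Signal.** `value = response_factor·μ(cn) + gc_slope·(gc − mean gc) +
  loading[batch]·probe_factor + N(0, σ)` with μ(1) = −1 (the ideal
  log₂(1/2)), μ(2) = 0. Defaults: response 0.75 (arrays compress the
  theoretical ratio), σ = 0.25 per probe, GC slope 0.5 per unit GC
  deviation, two batches with loading SD 0.1. These magnitudes make
  calling nontrivial but recoverable; all are configurable. `σ = 0` is
  explicitly allowed so the noise-free limit can be exercised exactly.
* **Determinism.** All randomness flows through
  `numpy.random.SeedSequence(seed, spawn_key=...)` streams; outputs are
  bit-for-bit reproducible from (config, seed).

What passing tests on this generator do **not** show about real data:
real probes have sequence-specific response, spatially correlated waves,
and cell-line artifacts none of which are modelled; real deletions need
not cover the gap nor share a common hotspot.

## Normalization

The original platform's normalization equations are proprietary and
undisclosed, so the package substitutes documented standard procedures
and says so: per-sample median centering, a per-sample regression of
log₂ ratio on GC fraction (closed-form linear by default; lowess with
span 0.3 optionally — linear is the default because it is exactly
testable), and removal of the top-k principal components (k = 2 default,
matching the simulated two-batch structure).

Two details matter and were decided here:

* **Every per-sample estimate excludes the candidate territory.** Both
  the median and the principal components are estimated using only probes
  outside the candidate-CNV intervals (by default the gap widened by the
  maximum deletion span). A large deletion covers up to ~38% of the
  region's probes; estimating the median over all probes shifts carrier
  columns upward, and — worse — that shift imprints a carrier-indicator
  rank-1 pattern across all probes which PCA then identifies as a
  leading component and regresses out, crushing the true signal. With
  the exclusion in place, the injected rank-1 batch artifact is removed
  to machine precision while the carrier-vs-noncarrier shift at the
  locus moves by well under 10%.
* **Only the GC-dependent part of the fit is subtracted** (the fitted
  line minus its own mean), so a GC-independent matrix passes through
  unchanged and the linear correction is idempotent.

PCA operates on probes × samples with components in sample space; probes
are rows, samples are columns, and the projection is applied to every
probe row. `k = 0` is an identity transform with a warning; constant GC
skips the GC fit with a warning in the report.

## Stage-1 screening caller

Locus summaries (per-sample mean log₂ ratio over probes whose midpoint
lies in the locus) are clustered by a hand-rolled one-dimensional EM
(quantile initialization at the {10, 50, 90}th percentiles, variance
floor 1e-8, tolerance 1e-6 on the log-likelihood, ≤ 500 iterations),
with the order k ∈ {1, 2, 3} chosen by BIC. The per-iteration
log-likelihood trace is stored and tested for monotonicity; the fit is
deterministic and permutation-invariant because the initialization is
quantile-based. A non-converged fit is flagged and calls everything
unchanged. Components map to classes by their means: within
`min_separation` (0.3 log₂ units, half the attenuated deletion shift at
default response) of 0 → unchanged, below → loss, above → gain.

The consecutive-evidence rule turns per-probe classes into intervals:
maximal runs of ≥ `min_run` (default 2 at this stage) loss probes span
first-probe start to last-probe end. The reliability screen retains
candidates with ≥ 50 probes **and** ≥ 50,000 bp, both inclusive — the
printed thresholds are worded ambiguously ("over"), and the inclusive
reading is used and configurable.

## Stage-2 tiling-aCGH caller

Tracks are smoothed with a centered moving average (w = 5 probes
default, odd, truncated at track ends); the 1-SD rule is applied to the
smoothed values, since the published copy-number plots display smoothed
data — `--no-smoothing` (w = 1) applies it to raw ratios instead. The
reference envelope stores the per-probe median, mean and sample SD
(n−1 denominator) of the smoothed panel tracks.

The loss call is `smoothed < median − 1·SD`, strict, so boundary values
(including everything when SD = 0) are unchanged. The published wording
mixes "1 SD from the median" (loss) with "mean ± 1 SD" (unchanged);
these are reconciled as: loss is the operative call against the median
(robust); the mean is carried in the envelope for reporting only. Gain
is never called — the analysis recognises two classes only.

**Run-length threshold.** By construction the 1-SD rule classifies a
diploid probe as loss with probability ≈ Φ(−1) ≈ 0.16, so short loss
runs are routine noise, and smoothing correlates neighbours (window 5),
making 10-probe runs common. The default `min_run` is therefore 30
probes (15 kb on the default tiling design) — an order of magnitude
below the smallest simulated deletion (200 kb) yet strict enough that
false runs are negligible. With this default, carrier-verdict accuracy
on the default-noise cohort is ≥ 95% (observed 100% over ten seeds);
with `min_run = 10` the same rule mislabels roughly a third of samples.
The value is configurable and the noise-free emulation is run at
`min_run = 10` to show the rule itself, not the run filter, drives the
calls there.

Segmentation partitions the region exactly: gap and masks become
`no_call` segments verbatim; within each probed stretch, boundaries
between runs are placed midway between the flanking probes. The **loss
extent (hull)** of a sample is min start to max end of its loss
segments, extended outward through directly abutting `no_call` segments:
a loss bounded by uncallable sequence plausibly continues into it and
its true edge cannot be observed there. The extent, not the union of
called loss segments, is what recovery is scored on (Jaccard against the
true deletion), because the gap and masks sit inside every simulated
deletion and are uncallable by construction.

A sample is a carrier when any loss segment overlaps the query locus
(default gap ± 150 kb) by ≥ 1 bp.

**Noise-free emulation.** The exact-cohort emulation (13 carrier cases,
1 carrier control, σ = 0) is run without the normalization stage: with
zero noise the matrix is rank-deficient, PCA removes arbitrary
directions, and the envelope SD collapses to rounding error, making
strict threshold comparisons depend on floating-point residue. The aCGH
stage proper (smoothing → envelope → classification → segmentation)
recovers exactly 13/100 and 1/100 carriers.

## Association

The two-sided Fisher exact p is the sum of hypergeometric point
probabilities not exceeding the observed one (relative tie tolerance
1e-7), computed by full enumeration in log-factorial arithmetic — the
common two-sided convention; doubling the one-sided p is an alternative
the package does not use. Both groups must be non-empty; a zero carrier
column collapses the enumeration to a single table and p = 1. The
implementation agrees with exact-integer enumeration for every
admissible table with n ≤ 40 (max |Δ| ≈ 5e-14).

The odds ratio is the cross product ad/bc; with any zero cell the
Haldane–Anscombe +0.5 correction applies to all cells for both point
and CI. The CI is the Woolf logit interval; each result records its
method string, because published intervals for this kind of table are
frequently computed by other (often unstated) procedures and are not
generally reproducible from the table alone. Bonferroni adjustment is
min(1, m·p) with m defaulting to the number of loci tested; m smaller
than that count is rejected as under-correction.

For the studied cohort table (13, 87, 1, 99): OR = 1287/87 ≈ 14.79,
two-sided p ≈ 1.28×10⁻³, and p·4 ≈ 5.1×10⁻³ < 0.05 for four candidate
loci. The package's exact p is about fivefold smaller than the
historically reported point value for the same counts, which is not
reproducible by standard two-sided enumeration; only the significance
bound (< 0.05 after correction) is treated as a reproducible quantity.

## Annotation and reporting

The packaged gene table transcribes the 34 putative genes of the region
(PDE6B at printed 609,373–654,571 through LETM1 at 1,784,558–1,827,772)
verbatim, including hypothetical LOC genes, with printed coordinates
converted on load; no re-annotation against any genome build is done.
Gene overlap is ≥ 1 bp, which reproduces the printed count of 34 for
the full region query. HbA1c values convert between reporting standards
as NGSP = JDS + 0.4 percentage points, with control eligibility defined
as NGSP strictly below 6.4%.

## Problem sizes

Tests and the acceptance script run the default 1.3-Mb region with
~2,489 tiling probes and 100 + 100 samples plus a 15-sample reference
panel; type-I error uses 500 replicate null cohorts at the association
stage only; the Fisher cross-check enumerates all ~134,000 admissible
tables with n ≤ 40. The full suite completes in well under a minute.

## Known limitations

* The normalization stand-ins are documented standard procedures, not
  the undisclosed platform equations; absolute intensities, dye effects
  and wave artifacts are out of scope.
* Breakpoints are resolved only to probe spacing (plus the midpoint
  convention); no CBS/HMM segmentation or base-pair refinement.
* The carrier verdict is locus-anchored; a deletion that never touches
  the query locus would not be counted, which is intended for this
  gap-anchored design but wrong for genome-wide use.
* The exact test is conservative (observed type-I ≈ 0.02 at α = 0.05),
  as expected for discrete exact tests; no mid-p variant is provided.
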