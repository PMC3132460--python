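# subtelcnv

Copy-number-loss calling and case-control association for a repeat-rich
subtelomeric region containing a genome gap.

## The problem

Subtelomeres are rich in low-copy repeats (LCRs) and often border genome
gaps — stretches of the reference assembly with no finished sequence,
where no array probe can be designed and copy-number status cannot be
inferred. Such regions are rearrangement hotspots, yet they are poorly
covered by standard SNP genotyping arrays, so deletions there are easy to
miss in case-control studies.

`subtelcnv` implements a two-stage, two-platform analysis of
heterozygous-deletion carriers over a 1.3-Mb subtelomeric model region
(positions 550,000–1,850,000 on a 4p16.3-like chromosome arm, with a
probe-free gap at 1,423,147–1,478,646 in printed 1-based coordinates and
LCR no-call masks flanking it), together with a synthetic-cohort
generator so that every stage is testable without external data. It is
aimed at statistical geneticists who want a reproducible, fully seeded
reimplementation of this style of CNV burden analysis.

## The method

**Stage 1 — genome-screening caller (sparse BeadChip-style design).**
Per-sample log₂-ratio matrices are normalized (median centering,
per-sample linear or lowess regression of log₂ ratio on probe GC
fraction, removal of the top-*k* principal components estimated on probes
outside candidate-CNV intervals). Per candidate locus, sample summaries
(mean log₂ ratio) are clustered with a one-dimensional Gaussian mixture
fitted by EM (quantile initialization, order *k* ∈ {1,2,3} chosen by
BIC); the component nearest 0 is "unchanged", a component below
−`min_separation` is "loss". Evidence requires a consecutive run of
abnormal probes, and a candidate is *reliable* only if it spans
≥ 50 kb over ≥ 50 consecutive probes.

**Stage 2 — tiling-aCGH validation (dense design).** Each track is
smoothed by a centered moving average (window *w* = 5 probes). A
reference envelope (per-probe median, mean and SD of smoothed ratios
across a panel of ≥ 2 normal individuals) defines the unchanged band;
a probe is called **loss** when its smoothed ratio falls strictly below
median − 1·SD. Maximal loss runs of ≥ `min_run` probes become loss
segments, the gap and LCR masks are emitted as `no_call`, and the
segments partition the region exactly. A sample is a **carrier** if any
loss segment overlaps the query locus (the gap ± 150 kb by default).

**Association.** Carrier status is cross-tabulated against case/control
status into a 2×2 table (a, b; c, d), tested with a two-sided Fisher's
exact test by full hypergeometric enumeration, Bonferroni-corrected over
the *m* loci tested, and summarized by the cross-product odds ratio
OR = ad/bc with a Woolf (logit) 95% CI,
exp(ln OR ± z₀.₉₇₅·√(1/a + 1/b + 1/c + 1/d)), applying the
Haldane–Anscombe +0.5 correction when a cell is zero.

**Simulator.** Carriers are drawn per status at configurable prevalence
(defaults: 0.13 in 100 cases, 0.01 in 100 controls); each carrier gets
one deletion spanning the gap (length uniform in 200–500 kb). Signal per
probe and sample is
`response_factor·μ(cn) + gc_slope·(gc − mean gc) + batch·probe + N(0, σ)`
with μ(1) = log₂(1/2) = −1, μ(2) = 0, response 0.75, σ = 0.25, and a
rank-1 two-batch artifact. Everything is bit-for-bit reproducible from
(config, seed).

## Worked example

Emulate the studied cohort (13 carrier cases, 1 carrier control,
noise-free) and run the tiling-aCGH stage plus association:

```python
from subtelcnv import SimulationConfig
from subtelcnv.pipeline import simulate_study, run_validation_study

config = SimulationConfig(sigma_probe=0.0, gc_slope=0.0,
                          batch_effect_sd=0.0, seed=1)
study = simulate_study(config, carrier_counts=(13, 1))
segments, verdicts, assoc = run_validation_study(
    study, window=5, min_run=10, normalize=False)

counts = verdicts.groupby("status")["carrier"].sum()
print(f"carriers: {counts['case']}/100 cases, {counts['control']}/100 controls")
t = assoc.table
print(f"2x2 table: a={t.a} b={t.b} c={t.c} d={t.d}")
print(f"Fisher two-sided p = {assoc.p:.3g}")
print(f"OR = {assoc.or_point:.1f}, 95% CI [{assoc.or_ci[0]:.2f}, "
      f"{assoc.or_ci[1]:.1f}] ({assoc.ci_method})")
```

prints

```
carriers: 13/100 cases, 1/100 controls
2x2 table: a=13 b=87 c=1 d=99
Fisher two-sided p = 0.00128
OR = 14.8, 95% CI [1.90, 115.4] (woolf)
```

The caller recovers every simulated carrier and no one else; the odds
ratio of carrier status for cases versus controls is 1287/87 ≈ 14.8, and
the exact test rejects the null of equal carrier prevalence (p ≈ 1.3×10⁻³;
still < 0.05 after Bonferroni correction over four candidate loci).

A shell workflow is available through the `subtelcnv` console script
(`simulate`, `normalize`, `screen`, `validate`, `associate`, `report`);
see `subtelcnv --help`.

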