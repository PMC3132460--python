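"""Synthetic array-cohort generator.

Emulates a two-platform case-control CNV study over a repeat-rich
subtelomeric region: a sparse "screening" BeadChip-like design and a dense
"tiling" aCGH design, heterozygous-deletion carriers at status-specific
prevalence, per-probe Gaussian noise, a GC-dependent intensity bias and a
low-rank batch effect.

Signal model per probe p and sample s::

    y[p, s] = response_factor * mu_per_cn[cn(p, s)]
              + gc_slope * (gc[p] - mean(gc))
              + batch_loading[batch(s)] * probe_factor[p]
              + N(0, sigma_probe)

where ``cn(p, s)`` is 1 when the probe midpoint falls inside one of the
sample's deletion intervals and 2 otherwise. A heterozygous deletion has
ideal log2 ratio log2(1/2) = -1; ``response_factor`` (default 0.75)
attenuates it to emulate array compression. Everything is reproducible
bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import Interval, overlaps
from .region import RegionModel, build_region_model

DEFAULT_SPACING = {"screening": 5_000, "tiling": 500}
PROBE_LENGTH = 60  # 60-mer oligonucleotide probes


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the studied cohort: 100 cases and 100 controls with
    carrier prevalence 0.13 among cases and 0.01 among controls.
    """

    n_cases: int = 100
    n_controls: int = 100
    p_case: float = 0.13
    p_control: float = 0.01
    deletion_min_bp: int = 200_000
    deletion_max_bp: int = 500_000
    cn_loss: int = 1
    mu_per_cn: dict = field(default_factory=lambda: {2: 0.0, 1: -1.0})
    response_factor: float = 0.75
    sigma_probe: float = 0.25
    gc_slope: float = 0.5
    n_batches: int = 2
    batch_effect_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_case <= 1.0 and 0.0 <= self.p_control <= 1.0):
            raise ValueError("carrier prevalences must lie in [0, 1]")
        if self.sigma_probe < 0:
            raise ValueError("sigma_probe must be non-negative")
        if self.mu_per_cn.get(2) != 0.0:
            raise ValueError("mu_per_cn[2] must be 0 (diploid reference)")
        if self.mu_per_cn.get(1) != -1.0:
            raise ValueError(
                "mu_per_cn[1] must be -1 (log2(1/2) for a heterozygous "
                "deletion before attenuation)"
            )
        if not 0.0 < self.response_factor <= 1.0:
            raise ValueError("response_factor must lie in (0, 1]")
        if self.cn_loss not in self.mu_per_cn:
            raise ValueError(f"mu_per_cn lacks an entry for cn_loss={self.cn_loss}")
        if not 0 < self.deletion_min_bp <= self.deletion_max_bp:
            raise ValueError("need 0 < deletion_min_bp <= deletion_max_bp")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("sample counts must be non-negative")


@dataclass(frozen=True)
class TruthProfile:
    """Ground-truth copy-number state for one simulated sample."""

    sample_id: str
    status: str  # "case" | "control"
    batch: int
    carrier: bool
    deletion_intervals: tuple[tuple[Interval, int], ...] = ()

    def __post_init__(self):
        if self.status not in ("case", "control"):
            raise ValueError(f"bad status {self.status!r}")
        if not self.carrier and self.deletion_intervals:
            raise ValueError("non-carrier with deletion intervals")


@dataclass(frozen=True)
class ArrayDesign:
    """Ordered, non-overlapping probes of one platform.

    ``starts``/``ends`` are half-open probe intervals; ``gc`` is the GC
    fraction of each probe sequence. No probe overlaps the region's gap.
    """

    platform: str
    probe_ids: tuple[str, ...]
    starts: np.ndarray
    ends: np.ndarray
    gc: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        gc = np.asarray(self.gc, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "gc", gc)
        if not (len(self.probe_ids) == len(starts) == len(ends) == len(gc)):
            raise ValueError("design fields have mismatched lengths")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("probes must be sorted and non-overlapping")
        if np.any((gc < 0) | (gc > 1)):
            raise ValueError("gc_fraction must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.probe_ids)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def probes_in(self, locus: Interval) -> np.ndarray:
        """Boolean mask of probes whose midpoint lies in ``locus``."""
        mid = self.midpoints
        return (mid >= locus[0]) & (mid < locus[1])


@dataclass
class IntensityMatrix:
    """Probes x samples log2-ratio grid plus sample metadata.

    ``values`` is a DataFrame indexed by probe_id with one column per
    sample; ``samples`` holds (sample_id, status, batch) in column order.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    design_ref: str = ""

    def __post_init__(self):
        if list(self.values.columns) != list(self.samples["sample_id"]):
            raise ValueError("matrix columns do not match sample sheet order")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("log2-ratio values must be finite")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "IntensityMatrix":
        ids = list(sample_ids)
        samples = (
            self.samples.set_index("sample_id").loc[ids].reset_index()
        )
        return IntensityMatrix(self.values[ids], samples, self.design_ref)

    def copy_with_values(self, values: np.ndarray) -> "IntensityMatrix":
        vals = pd.DataFrame(
            values, index=self.values.index, columns=self.values.columns
        )
        return IntensityMatrix(vals, self.samples.copy(), self.design_ref)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def build_array_design(
    region: RegionModel,
    platform: str,
    spacing_bp: int | None = None,
    probe_length: int = PROBE_LENGTH,
    seed: int = 0,
) -> ArrayDesign:
    """Tile the region with probes at fixed spacing, skipping the gap.

    Probes overlapping LCR masks are retained (calling masks them later);
    probes overlapping the gap are dropped — no probe can be designed in
    unfinished sequence. GC fraction follows a smooth positional wave plus
    seeded jitter.
    """
    if platform not in DEFAULT_SPACING:
        raise ValueError(f"platform must be screening or tiling, got {platform!r}")
    if spacing_bp is None:
        spacing_bp = DEFAULT_SPACING[platform]
    if spacing_bp <= 0:
        raise ValueError("spacing_bp must be positive")
    if spacing_bp >= region.span_bp:
        raise ValueError(
            f"spacing {spacing_bp} bp exceeds region span {region.span_bp} bp: "
            "empty design"
        )
    starts = np.arange(
        region.region_start, region.region_end - probe_length + 1, spacing_bp,
        dtype=np.int64,
    )
    ends = starts + probe_length
    keep = (ends <= region.gap[0]) | (starts >= region.gap[1])
    starts, ends = starts[keep], ends[keep]
    if len(starts) == 0:
        raise ValueError("empty design: no probe fits outside the gap")

    rng = _rng(seed, 0)
    rel = (starts - region.region_start) / 300_000.0
    gc = 0.45 + 0.08 * np.sin(2 * np.pi * rel) + rng.normal(0.0, 0.02, len(starts))
    gc = np.clip(gc, 0.0, 1.0)
    ids = tuple(f"{platform[:4]}_{i:05d}" for i in range(len(starts)))
    return ArrayDesign(platform, ids, starts, ends, gc)


def _sample_deletion(
    rng: np.random.Generator, region: RegionModel, config: SimulationConfig
) -> Interval:
    """One deletion interval anchored on the gap.

    Length is uniform in [deletion_min_bp, deletion_max_bp]; the interval
    always covers the whole gap (the gap is a rearrangement hotspot) and is
    clipped to the region, so it never lies entirely inside the gap.
    """
    span = int(rng.integers(config.deletion_min_bp, config.deletion_max_bp + 1))
    span = max(span, region.gap_bp + 1)
    lo = region.gap[1] - span
    hi = region.gap[0]
    start = int(rng.integers(lo, hi + 1))
    end = start + span
    return (max(start, region.region_start), min(end, region.region_end))


def simulate_cohort(
    config: SimulationConfig,
    region: RegionModel | None = None,
    carrier_counts: tuple[int, int] | None = None,
) -> list[TruthProfile]:
    """Draw ground-truth carrier profiles for the case-control cohort.

    Carrier status is Bernoulli per sample with status-specific prevalence;
    ``carrier_counts=(k_cases, k_controls)`` instead fixes exact carrier
    counts (carriers assigned to a random subset), for emulating a printed
    cohort table. Batches are assigned round-robin. Deterministic given
    ``config.seed``.
    """
    region = region or build_region_model()
    rng = _rng(config.seed, 1)
    profiles: list[TruthProfile] = []
    groups = [
        ("case", config.n_cases, config.p_case, None),
        ("control", config.n_controls, config.p_control, None),
    ]
    if carrier_counts is not None:
        k_case, k_control = carrier_counts
        if k_case > config.n_cases or k_control > config.n_controls:
            raise ValueError("carrier_counts exceed group sizes")
        groups = [
            ("case", config.n_cases, None, k_case),
            ("control", config.n_controls, None, k_control),
        ]
    idx = 0
    for status, n, prevalence, fixed_k in groups:
        if fixed_k is None:
            carriers = rng.random(n) < prevalence
        else:
            carriers = np.zeros(n, dtype=bool)
            carriers[rng.choice(n, size=fixed_k, replace=False)] = True
        for i in range(n):
            sid = f"{status}_{i:03d}"
            batch = idx % config.n_batches
            if carriers[i]:
                iv = _sample_deletion(rng, region, config)
                profiles.append(
                    TruthProfile(sid, status, batch, True, ((iv, config.cn_loss),))
                )
            else:
                profiles.append(TruthProfile(sid, status, batch, False))
            idx += 1
    return profiles


def copy_number_at_probes(
    design: ArrayDesign, truth: TruthProfile
) -> np.ndarray:
    """Integer copy number at every probe midpoint for one sample."""
    cn = np.full(len(design), 2, dtype=np.int64)
    for iv, value in truth.deletion_intervals:
        cn[design.probes_in(iv)] = value
    return cn


def simulate_log2_matrix(
    design: ArrayDesign,
    truths: list[TruthProfile],
    config: SimulationConfig,
) -> IntensityMatrix:
    """Generate the noisy log2-ratio matrix for a cohort on one design."""
    if not truths:
        raise ValueError("truths must be non-empty")
    if len(design) == 0:
        raise ValueError("design must be non-empty")
    rng = _rng(config.seed, 2)
    n_probes, n_samples = len(design), len(truths)

    mu = np.empty((n_probes, n_samples))
    for j, truth in enumerate(truths):
        cn = copy_number_at_probes(design, truth)
        mu[:, j] = config.response_factor * np.vectorize(config.mu_per_cn.get)(cn)

    gc_term = config.gc_slope * (design.gc - design.gc.mean())
    values = mu + gc_term[:, None]

    if config.n_batches > 0 and config.batch_effect_sd > 0:
        probe_factor = rng.normal(0.0, 1.0, n_probes)
        loadings = rng.normal(0.0, config.batch_effect_sd, config.n_batches)
        batch_of = np.array([t.batch for t in truths])
        values = values + np.outer(probe_factor, loadings[batch_of])

    if config.sigma_probe > 0:
        values = values + rng.normal(0.0, config.sigma_probe, (n_probes, n_samples))

    frame = pd.DataFrame(
        values,
        index=pd.Index(design.probe_ids, name="probe_id"),
        columns=[t.sample_id for t in truths],
    )
    samples = pd.DataFrame(
        {
            "sample_id": [t.sample_id for t in truths],
            "status": [t.status for t in truths],
            "batch": [t.batch for t in truths],
        }
    )
    return IntensityMatrix(frame, samples, design_ref=design.platform)


def simulate_normal_panel(
    n_panel: int, config: SimulationConfig, start_index: int = 0
) -> list[TruthProfile]:
    """Non-carrier reference individuals for the aCGH envelope panel."""
    return [
        TruthProfile(f"panel_{start_index + i:03d}", "control",
                     (i % config.n_batches), False)
        for i in range(n_panel)
    ]
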