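"""End-to-end composition of the two-stage study.

``simulate_study`` generates a cohort plus reference panel on one design;
``normalize_matrix`` chains median centering, GC correction and PCA batch
removal; ``run_validation_study`` runs the tiling-aCGH stage and returns
segments, verdicts and the carrier association; ``evaluate_verdicts``
scores verdicts and called loss spans against the simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acgh import CopyNumberSegment, loss_hull, validate_samples
from .association import AssociationResult, associate_loci, build_table
from .intervals import Interval, length, overlap_bp
from .normalize import gc_correct, median_center, remove_batch_pca
from .region import RegionModel, build_region_model, default_query_locus
from .simulate import (
    ArrayDesign,
    IntensityMatrix,
    SimulationConfig,
    TruthProfile,
    build_array_design,
    simulate_cohort,
    simulate_log2_matrix,
    simulate_normal_panel,
)


@dataclass
class StudyData:
    """Simulated inputs for one platform: cohort + reference panel."""

    region: RegionModel
    design: ArrayDesign
    truths: list[TruthProfile]
    panel_truths: list[TruthProfile]
    matrix: IntensityMatrix  # cohort + panel columns, cohort first
    config: SimulationConfig | None = None

    @property
    def cohort_ids(self) -> list[str]:
        return [t.sample_id for t in self.truths]

    @property
    def panel_ids(self) -> list[str]:
        return [t.sample_id for t in self.panel_truths]

    def cohort_matrix(self) -> IntensityMatrix:
        return self.matrix.subset_samples(self.cohort_ids)

    def panel_matrix(self) -> IntensityMatrix:
        return self.matrix.subset_samples(self.panel_ids)


def simulate_study(
    config: SimulationConfig,
    region: RegionModel | None = None,
    platform: str = "tiling",
    n_panel: int = 15,
    carrier_counts: tuple[int, int] | None = None,
    spacing_bp: int | None = None,
) -> StudyData:
    """Simulate the cohort and an ``n_panel``-sample normal reference panel."""
    region = region or build_region_model()
    design = build_array_design(
        region, platform, spacing_bp=spacing_bp, seed=config.seed
    )
    truths = simulate_cohort(config, region, carrier_counts=carrier_counts)
    panel = simulate_normal_panel(n_panel, config)
    matrix = simulate_log2_matrix(design, truths + panel, config)
    return StudyData(region, design, truths, panel, matrix, config)


def candidate_territory(study: StudyData) -> Interval:
    """Largest interval in which simulated deletions can lie: the gap
    widened by the maximum deletion span, clipped to the region."""
    config = study.config or SimulationConfig()
    max_span = config.deletion_max_bp
    region = study.region
    return (
        max(region.region_start, region.gap[1] - max_span),
        min(region.region_end, region.gap[0] + max_span),
    )


def normalize_matrix(
    matrix: IntensityMatrix,
    design: ArrayDesign,
    gc_method: str = "linear",
    pca_k: int = 2,
    exclude_intervals: list[Interval] = (),
) -> IntensityMatrix:
    """Median centering, then GC correction, then PCA batch removal.

    ``exclude_intervals`` is honoured by every step that estimates a
    per-sample quantity (median, principal components) so that true
    copy-number signal in the candidate territory is preserved.
    """
    centered = median_center(
        matrix, design=design, exclude_intervals=exclude_intervals
    )
    corrected, _ = gc_correct(centered, design, method=gc_method)
    removed, _ = remove_batch_pca(
        corrected, k=pca_k, exclude_intervals=exclude_intervals, design=design
    )
    return removed


def run_validation_study(
    study: StudyData,
    window: int = 5,
    min_run: int = 30,
    locus: Interval | None = None,
    normalize: bool = True,
    pca_k: int = 2,
    exclude_intervals: list[Interval] | None = None,
) -> tuple[dict[str, list[CopyNumberSegment]], pd.DataFrame, AssociationResult]:
    """Tiling-aCGH stage on a simulated study.

    Normalizes cohort and panel jointly, builds the envelope from the
    panel, calls segments and carrier verdicts for the cohort, and tests
    the carrier association. By default the whole candidate-CNV territory
    (gap widened by the maximum simulated deletion span) is excluded from
    PC estimation so true deletion signal is not regressed out; the
    narrower carrier-query ``locus`` defaults to the gap +- 150 kb.
    """
    locus = locus if locus is not None else default_query_locus(study.region)
    matrix = study.matrix
    if normalize:
        if exclude_intervals is None:
            exclude_intervals = [candidate_territory(study)]
        matrix = normalize_matrix(
            matrix, study.design, pca_k=pca_k, exclude_intervals=exclude_intervals
        )
    cohort = matrix.subset_samples(study.cohort_ids)
    panel = matrix.subset_samples(study.panel_ids)
    segments, verdicts = validate_samples(
        cohort, panel, study.design, study.region,
        window=window, min_run=min_run, locus=locus,
    )
    result = associate_loci({locus: verdicts}, cohort.samples)[0]
    return segments, verdicts, result


def evaluate_verdicts(
    truths: list[TruthProfile],
    verdicts: pd.DataFrame,
    segment_sets: dict[str, list[CopyNumberSegment]] | None = None,
) -> dict:
    """Score verdicts (accuracy) and loss spans (Jaccard) against truth.

    Jaccard compares, per true carrier, the hull of called loss segments
    with the true deletion interval; uncallable no_call stretches (gap,
    LCR masks) inside the hull therefore do not count against the call.
    """
    truth_by_id = {t.sample_id: t for t in truths}
    correct = 0
    for _, row in verdicts.iterrows():
        if bool(row["carrier"]) == truth_by_id[row["sample_id"]].carrier:
            correct += 1
    out = {
        "n_samples": len(verdicts),
        "accuracy": correct / len(verdicts) if len(verdicts) else float("nan"),
    }
    if segment_sets is not None:
        jaccards = []
        for t in truths:
            if not t.carrier:
                continue
            true_iv = t.deletion_intervals[0][0]
            hull = loss_hull(segment_sets.get(t.sample_id, []))
            if hull is None:
                jaccards.append(0.0)
                continue
            inter = overlap_bp(hull, true_iv)
            union = length(hull) + length(true_iv) - inter
            jaccards.append(inter / union if union else 0.0)
        out["jaccard_median"] = float(np.median(jaccards)) if jaccards else float("nan")
        out["n_carriers_true"] = len(jaccards)
    return out


def type_one_error_rate(
    n_replicates: int = 500,
    prevalence: float = 0.05,
    n_cases: int = 100,
    n_controls: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical rejection rate of the exact test under the null.

    Carrier status is drawn at equal prevalence in both groups and the
    association stage alone is run (m = 1) per replicate cohort.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    from .association import ContingencyTable, fisher_exact_two_sided

    for _ in range(n_replicates):
        a = int(rng.binomial(n_cases, prevalence))
        c = int(rng.binomial(n_controls, prevalence))
        table = ContingencyTable(a, n_cases - a, c, n_controls - c)
        if fisher_exact_two_sided(table) < alpha:
            rejections += 1
    rate = rejections / n_replicates
    se = float(np.sqrt(alpha * (1 - alpha) / n_replicates))
    return {"rate": rate, "n_replicates": n_replicates, "mc_se": se}
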