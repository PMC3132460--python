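"""Readers and writers for the package's plain-text interchange formats.

Probe maps, truth profiles and segments travel as BED (0-based half-open);
log2-ratio matrices, sample sheets, envelopes and association tables as
TSV; region models as YAML (see :mod:`subtelcnv.region`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .acgh import CopyNumberSegment, ReferenceEnvelope
from .association import AssociationResult
from .simulate import ArrayDesign, IntensityMatrix, TruthProfile


def write_design_bed(design: ArrayDesign, path, chrom: str = "chr4") -> None:
    """Probe map as BED: name = probe_id, score = GC fraction x 1000."""
    frame = pd.DataFrame(
        {
            "chrom": chrom,
            "start": design.starts,
            "end": design.ends,
            "name": list(design.probe_ids),
            "score": np.round(design.gc * 1000).astype(int),
        }
    )
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_design_bed(path, platform: str = "tiling") -> ArrayDesign:
    frame = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score"],
    )
    return ArrayDesign(
        platform=platform,
        probe_ids=tuple(frame["name"].astype(str)),
        starts=frame["start"].to_numpy(),
        ends=frame["end"].to_numpy(),
        gc=frame["score"].to_numpy() / 1000.0,
    )


def write_matrix_tsv(matrix: IntensityMatrix, path) -> None:
    """Log2-ratio matrix: first column probe_id, one column per sample."""
    matrix.values.to_csv(path, sep="\t", index=True, float_format="%.6g")


def write_sample_sheet(matrix_or_frame, path) -> None:
    frame = (
        matrix_or_frame.samples
        if isinstance(matrix_or_frame, IntensityMatrix)
        else matrix_or_frame
    )
    frame.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path, sample_sheet_path) -> IntensityMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    samples = pd.read_csv(sample_sheet_path, sep="\t")
    samples = samples.set_index("sample_id").loc[list(values.columns)].reset_index()
    return IntensityMatrix(values, samples)


def write_truth_bed(truths: list[TruthProfile], path, chrom: str = "chr4") -> None:
    """Per-sample true deletion intervals (non-carriers contribute no rows)."""
    rows = [
        {"chrom": chrom, "start": iv[0], "end": iv[1],
         "name": t.sample_id, "score": cn}
        for t in truths
        for iv, cn in t.deletion_intervals
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_segments_bed(
    segment_sets: dict[str, list[CopyNumberSegment]], path, chrom: str = "chr4"
) -> None:
    """Per-sample segments as BED: name = class, score = probe support."""
    rows = [
        {"chrom": chrom, "start": seg.start, "end": seg.end,
         "name": f"{sid}:{seg.cls}", "score": seg.n_probes}
        for sid, segments in segment_sets.items()
        for seg in segments
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_envelope_tsv(
    envelope: ReferenceEnvelope, design: ArrayDesign, path
) -> None:
    pd.DataFrame(
        {
            "probe_id": list(design.probe_ids),
            "median": envelope.median,
            "mean": envelope.mean,
            "sd": envelope.sd,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_verdicts_tsv(verdicts: pd.DataFrame, path) -> None:
    verdicts.to_csv(path, sep="\t", index=False)


def read_verdicts_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    frame["carrier"] = frame["carrier"].astype(bool)
    return frame


def write_association_tsv(results: list[AssociationResult], path) -> None:
    rows = [
        {
            "locus_start": r.locus[0],
            "locus_end": r.locus[1],
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "p": r.p,
            "m": r.m,
            "p_bonferroni": r.p_bonferroni,
            "odds_ratio": r.or_point,
            "ci_low": r.or_ci[0],
            "ci_high": r.or_ci[1],
            "ci_method": r.ci_method,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
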