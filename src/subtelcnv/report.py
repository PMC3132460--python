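"""Annotation and reporting.

Gene-overlap counting against the packaged 4p16.3 gene table (34 putative
genes between PDE6B and LETM1, printed 1-based inclusive coordinates
converted to half-open on load), gap-overlap computation for per-sample
segments, the JDS-to-NGSP HbA1c unit conversion used for control
eligibility, and tabular per-cohort segment reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .acgh import LOSS, CopyNumberSegment
from .intervals import Interval, from_printed, overlap_bp, overlaps
from .region import RegionModel

#: NGSP HbA1c (%) = JDS HbA1c (%) + 0.4
HBA1C_JDS_TO_NGSP_OFFSET = 0.4
#: nondiabetic-control eligibility: NGSP HbA1c strictly below 6.4%
HBA1C_CONTROL_CUTOFF = 6.4

GENE_TABLE_COLUMNS = [
    "start", "end", "cytoband", "symbol", "description", "model_evidence"
]


@dataclass(frozen=True)
class GeneRecord:
    """One putative gene; ``interval`` is internal half-open coordinates."""

    symbol: str
    interval: Interval
    cytoband: str = ""
    description: str = ""
    model_evidence: str = ""
    printed_start: int = 0
    printed_end: int = 0

    def __post_init__(self):
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")
        if self.interval[0] >= self.interval[1]:
            raise ValueError(
                f"gene {self.symbol}: start must precede end, got {self.interval}"
            )


def packaged_gene_table_path():
    """Path of the gene-annotation fixture shipped with the package."""
    return resources.files("subtelcnv.data") / "genes_4p16_3.tsv"


def load_gene_table(path=None) -> list[GeneRecord]:
    """Parse a gene table TSV (printed 1-based inclusive coordinates).

    Columns: start, end, cytoband, symbol, description, model_evidence.
    Records are returned sorted by start. Defaults to the packaged 4p16.3
    fixture.
    """
    if path is None:
        path = packaged_gene_table_path()
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.empty and list(frame.columns) != GENE_TABLE_COLUMNS:
        return []
    missing = [c for c in GENE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"gene table lacks columns: {missing}")
    records = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"gene table line {line}: bad coordinates") from exc
        if start >= end:
            raise ValueError(
                f"gene table line {line}: start {start:,} must precede end "
                f"{end:,}"
            )
        records.append(
            GeneRecord(
                symbol=str(row["symbol"]),
                interval=from_printed(start, end),
                cytoband=str(row["cytoband"]),
                description=str(row["description"]),
                model_evidence=str(row["model_evidence"]),
                printed_start=start,
                printed_end=end,
            )
        )
    records.sort(key=lambda r: r.interval[0])
    return records


def genes_in_region(genes: list[GeneRecord], interval: Interval) -> list[GeneRecord]:
    """Genes overlapping the query interval by at least 1 bp."""
    if interval[0] > interval[1]:
        raise ValueError(f"malformed query interval {interval}")
    return [g for g in genes if overlaps(g.interval, interval)]


def hba1c_jds_to_ngsp(value_jds: float) -> float:
    """Convert an HbA1c percentage from the JDS to the NGSP standard."""
    if value_jds < 0:
        raise ValueError(f"HbA1c cannot be negative, got {value_jds}")
    return value_jds + HBA1C_JDS_TO_NGSP_OFFSET

def control_eligible(value_ngsp: float) -> bool:
    """Nondiabetic-control eligibility: NGSP HbA1c strictly below 6.4%."""
    return value_ngsp < HBA1C_CONTROL_CUTOFF


def render_cohort_report(
    segment_sets: dict[str, list[CopyNumberSegment]],
    region: RegionModel,
    genes: list[GeneRecord],
    sample_sheet: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate per-sample segments and a cohort carrier summary.

    Returns (segments table, summary table). The segments table has one
    row per sample per segment with its class, span, probe support, gap
    overlap and overlapped gene symbols. The summary counts carriers
    (samples with at least one loss segment) by case/control status.
    """
    rows = []
    for sample_id, segments in segment_sets.items():
        for seg in segments:
            symbols = ",".join(
                g.symbol for g in genes_in_region(genes, seg.interval)
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "chrom": region.chrom_label,
                    "start": seg.start,
                    "end": seg.end,
                    "class": seg.cls,
                    "span_bp": seg.span_bp,
                    "n_probes": seg.n_probes,
                    "gap_overlap_bp": region.gap_overlap_bp(seg.interval),
                    "genes": symbols,
                }
            )
    seg_table = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "chrom", "start", "end", "class", "span_bp",
            "n_probes", "gap_overlap_bp", "genes",
        ],
    )

    status_of = {}
    if sample_sheet is not None:
        status_of = dict(zip(sample_sheet["sample_id"], sample_sheet["status"]))

    def _status(sample_id: str) -> str | None:
        if sample_id in status_of:
            return status_of[sample_id]
        # fall back on the simulator's sample-naming convention
        for prefix in ("case", "control"):
            if sample_id.startswith(prefix):
                return prefix
        return None

    summary_rows = []
    for status in ("case", "control"):
        ids = [s for s in segment_sets if _status(s) == status]
        if not ids:
            continue
        carriers = sum(
            1 for s in ids if any(seg.cls == LOSS for seg in segment_sets[s])
        )
        summary_rows.append(
            {"status": status, "n_samples": len(ids), "n_carriers": carriers}
        )
    summary = pd.DataFrame(summary_rows, columns=["status", "n_samples", "n_carriers"])
    return seg_table, summary


__all__ = [
    "GeneRecord",
    "load_gene_table",
    "packaged_gene_table_path",
    "genes_in_region",
    "overlap_bp",
    "hba1c_jds_to_ngsp",
    "control_eligible",
    "render_cohort_report",
]
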