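"""Model of the studied subtelomeric region.

The default region is a 1.3-Mb interval on a 4p16.3-like subtelomere,
spanning positions 550,000-1,850,000 and containing a probe-free genome
gap (printed coordinates 1,423,147-1,478,646, 1-based inclusive) plus
low-copy-repeat (LCR) intervals flanking the gap in which copy-number
status is never inferred (no_call).

Coordinates are one internal synthetic coordinate system labelled by
``build_label``; no liftover between assembly builds is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .intervals import Interval, contains, from_printed, length, overlap_bp

#: printed gap coordinates, 1-based inclusive ("gap-177")
GAP_PRINTED = (1_423_147, 1_478_646)

DEFAULT_REGION: Interval = (550_000, 1_850_000)
DEFAULT_GAP: Interval = from_printed(*GAP_PRINTED)
#: default LCR no-call masks: two intervals abutting the gap on either side
DEFAULT_LCR_MASKS: tuple[Interval, ...] = (
    (1_395_000, DEFAULT_GAP[0]),
    (DEFAULT_GAP[1], 1_505_000),
)


@dataclass(frozen=True)
class RegionModel:
    """A genomic region with one probe-free gap and LCR no-call masks."""

    chrom_label: str = "chr4"
    region_start: int = DEFAULT_REGION[0]
    region_end: int = DEFAULT_REGION[1]
    gap: Interval = DEFAULT_GAP
    lcr_masks: tuple[Interval, ...] = DEFAULT_LCR_MASKS
    build_label: str = "synthetic (NCBI Build 36.1 coordinates)"

    def __post_init__(self):
        object.__setattr__(self, "gap", tuple(self.gap))
        object.__setattr__(
            self, "lcr_masks", tuple(tuple(m) for m in self.lcr_masks)
        )
        if not self.region_start < self.region_end:
            raise ValueError(
                f"region_start must precede region_end, got "
                f"[{self.region_start}, {self.region_end})"
            )
        span = (self.region_start, self.region_end)
        for name, iv in [("gap", self.gap)] + [
            (f"lcr_mask[{i}]", m) for i, m in enumerate(self.lcr_masks)
        ]:
            if iv[0] > iv[1]:
                raise ValueError(f"{name} has negative length: {iv}")
            if not contains(span, iv):
                raise ValueError(f"{name} {iv} not contained in region {span}")
        masks = sorted(self.lcr_masks)
        for prev, nxt in zip(masks, masks[1:]):
            if prev[1] > nxt[0]:
                raise ValueError(f"lcr_masks overlap: {prev} and {nxt}")

    @property
    def span(self) -> Interval:
        return (self.region_start, self.region_end)

    @property
    def span_bp(self) -> int:
        return self.region_end - self.region_start

    @property
    def gap_bp(self) -> int:
        return length(self.gap)

    def no_call_intervals(self) -> list[Interval]:
        """Gap plus LCR masks, sorted; where calling emits no_call."""
        return sorted([self.gap, *self.lcr_masks])

    def gap_overlap_bp(self, iv: Interval) -> int:
        return overlap_bp(self.gap, iv)


def build_region_model(**overrides) -> RegionModel:
    """Build the region model, optionally overriding any field.

    ``gap_printed=(start, end)`` may be given instead of ``gap`` to supply
    1-based inclusive coordinates, converted to half-open internally.
    """
    if "gap_printed" in overrides:
        if "gap" in overrides:
            raise ValueError("give either gap or gap_printed, not both")
        overrides["gap"] = from_printed(*overrides.pop("gap_printed"))
    return RegionModel(**overrides)


def default_query_locus(region: RegionModel, flank: int = 150_000) -> Interval:
    """Candidate-CNV locus: the gap widened by ``flank`` on each side."""
    return (
        max(region.region_start, region.gap[0] - flank),
        min(region.region_end, region.gap[1] + flank),
    )


def region_to_yaml(region: RegionModel, path) -> None:
    doc = {
        "chrom_label": region.chrom_label,
        "region_start": region.region_start,
        "region_end": region.region_end,
        "gap": list(region.gap),
        "lcr_masks": [list(m) for m in region.lcr_masks],
        "build_label": region.build_label,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def region_from_yaml(path) -> RegionModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return build_region_model(**doc)


def with_masks(region: RegionModel, masks: list[Interval]) -> RegionModel:
    return replace(region, lcr_masks=tuple(tuple(m) for m in masks))
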