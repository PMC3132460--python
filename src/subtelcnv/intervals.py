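"""Half-open interval arithmetic on base-pair coordinates.

All internal coordinates are 0-based half-open ``[start, end)``, the BED
convention. Printed 1-based inclusive coordinates (the usual form in
tables and figure legends) are converted on load via :func:`from_printed`.
"""

from __future__ import annotations

Interval = tuple[int, int]


def validate_interval(iv: Interval, name: str = "interval") -> None:
    start, end = iv
    if start > end:
        raise ValueError(f"{name} has negative length: [{start}, {end})")


def from_printed(start_1based: int, end_inclusive: int) -> Interval:
    """Convert a printed 1-based inclusive interval to 0-based half-open."""
    if start_1based < 1 or end_inclusive < start_1based:
        raise ValueError(
            f"bad printed coordinates {start_1based:,}-{end_inclusive:,}"
        )
    return (start_1based - 1, end_inclusive)


def length(iv: Interval) -> int:
    return iv[1] - iv[0]


def overlap_bp(a: Interval, b: Interval) -> int:
    """Length in bp of the intersection of two half-open intervals (>= 0)."""
    validate_interval(a, "first interval")
    validate_interval(b, "second interval")
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def overlaps(a: Interval, b: Interval) -> bool:
    return overlap_bp(a, b) > 0


def contains(outer: Interval, inner: Interval) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def intersect(a: Interval, b: Interval) -> Interval | None:
    start, end = max(a[0], b[0]), min(a[1], b[1])
    return (start, end) if start < end else None


def complement_within(outer: Interval, cutouts: list[Interval]) -> list[Interval]:
    """Sub-intervals of ``outer`` not covered by any of ``cutouts``.

    Cutouts are clipped to ``outer`` and may touch but not overlap.
    """
    clipped = sorted(c for c in (intersect(outer, iv) for iv in cutouts) if c)
    out: list[Interval] = []
    cursor = outer[0]
    for start, end in clipped:
        if start < cursor:
            raise ValueError("cutout intervals overlap")
        if start > cursor:
            out.append((cursor, start))
        cursor = end
    if cursor < outer[1]:
        out.append((cursor, outer[1]))
    return out
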