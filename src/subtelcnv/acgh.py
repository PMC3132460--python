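"""Stage-2 tiling-aCGH caller.

Per-sample log2-ratio tracks on the dense tiling design are smoothed with
a centered moving average, a reference envelope (per-probe median, mean
and SD of the smoothed ratios across a panel of normal individuals) is
built, and a probe is called "loss" when its smoothed ratio falls
strictly below median - 1*SD. Maximal loss runs of at least ``min_run``
probes become loss segments; probes inside low-copy-repeat (LCR) masks
and the probe-free genome gap are emitted as no_call; everything else is
"unchanged". Per sample, the segments partition the region exactly.

Only two called classes exist (loss and unchanged) — copy-number gain is
not called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import Interval, complement_within, overlap_bp
from .region import RegionModel, default_query_locus
from .simulate import ArrayDesign, IntensityMatrix

LOSS, UNCHANGED, NO_CALL = "loss", "unchanged", "no_call"


def moving_average(values, w: int) -> np.ndarray:
    """Centered moving average over ``w`` probes, truncated at the ends.

    ``w`` must be odd so the window is symmetric; near the track ends the
    mean is taken over the probes available.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("track must be one-dimensional")
    if w < 1 or w > values.size:
        raise ValueError(f"window must satisfy 1 <= w <= {values.size}")
    if w % 2 == 0:
        raise ValueError(f"window must be odd, got {w}; use w={w + 1} or {w - 1}")
    return (
        pd.Series(values).rolling(window=w, center=True, min_periods=1).mean()
        .to_numpy()
    )


@dataclass
class SmoothedTrack:
    """One sample's moving-average log2-ratio track."""

    sample_id: str
    values: np.ndarray
    window: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")


def smooth_matrix(matrix: IntensityMatrix, w: int) -> list[SmoothedTrack]:
    """Moving-average every sample column of an intensity matrix."""
    X = matrix.values.to_numpy()
    return [
        SmoothedTrack(sid, moving_average(X[:, j], w), w)
        for j, sid in enumerate(matrix.samples["sample_id"])
    ]


@dataclass
class ReferenceEnvelope:
    """Per-probe location and spread of smoothed ratios in a normal panel."""

    median: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_panel: int
    window: int

    def __post_init__(self):
        for name in ("median", "mean", "sd"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.median.shape == self.mean.shape == self.sd.shape):
            raise ValueError("envelope fields must have equal length")
        if np.any(self.sd < 0):
            raise ValueError("per-probe SD must be non-negative")
        if self.n_panel < 2:
            raise ValueError("reference panel must contain at least 2 samples")


def build_envelope(normal_tracks: list[SmoothedTrack]) -> ReferenceEnvelope:
    """Per-probe median, mean and sample SD (n-1) across the normal panel."""
    if len(normal_tracks) < 2:
        raise ValueError("need at least 2 normal samples for an envelope")
    lengths = {t.values.size for t in normal_tracks}
    windows = {t.window for t in normal_tracks}
    if len(lengths) > 1 or len(windows) > 1:
        raise ValueError("panel tracks must share one design and window")
    panel = np.column_stack([t.values for t in normal_tracks])
    return ReferenceEnvelope(
        median=np.median(panel, axis=1),
        mean=panel.mean(axis=1),
        sd=panel.std(axis=1, ddof=1),
        n_panel=panel.shape[1],
        window=windows.pop(),
    )


def classify_probes(track: SmoothedTrack, envelope: ReferenceEnvelope) -> np.ndarray:
    """Loss iff the smoothed ratio falls strictly below median - 1*SD.

    The comparison is strict ("exceeded a threshold"), so a value exactly
    on the boundary — including every value when SD is 0 — is unchanged.
    """
    if track.values.size != envelope.median.size:
        raise ValueError("track and envelope must be on the same design")
    loss = track.values < envelope.median - envelope.sd
    return np.where(loss, LOSS, UNCHANGED).astype(object)


@dataclass
class CopyNumberSegment:
    """One called segment of a sample's copy-number profile."""

    sample_id: str
    start: int
    end: int
    cls: str
    n_probes: int
    mean_ratio: float = float("nan")

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("segment must have positive length")
        if self.cls not in (LOSS, UNCHANGED, NO_CALL):
            raise ValueError(f"bad segment class {self.cls!r}")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)

    @property
    def span_bp(self) -> int:
        return self.end - self.start


def _runs(labels) -> list[tuple[int, int, object]]:
    """Maximal runs of equal labels as (first, last_inclusive, label)."""
    out = []
    i = 0
    while i < len(labels):
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        out.append((i, j, labels[i]))
        i = j + 1
    return out


def segment_calls(
    classes,
    design: ArrayDesign,
    region: RegionModel,
    min_run: int = 30,
    sample_id: str = "",
    smoothed: np.ndarray | None = None,
) -> list[CopyNumberSegment]:
    """Partition the region into loss / unchanged / no_call segments.

    The gap and each LCR mask become no_call segments verbatim. Within
    each remaining probed stretch, loss runs shorter than ``min_run`` are
    demoted to unchanged, and boundaries between adjacent runs are placed
    midway between the flanking probes.
    """
    classes = np.asarray(classes, dtype=object)
    if classes.shape != (len(design),):
        raise ValueError("classes must align with design probes")
    mids = design.midpoints
    no_call_ivs = region.no_call_intervals()
    segments: list[CopyNumberSegment] = []

    for iv in no_call_ivs:
        n_inside = int(((mids >= iv[0]) & (mids < iv[1])).sum())
        segments.append(
            CopyNumberSegment(sample_id, iv[0], iv[1], NO_CALL, n_inside)
        )

    for block in complement_within(region.span, no_call_ivs):
        idx = np.nonzero((mids >= block[0]) & (mids < block[1]))[0]
        if idx.size == 0:
            segments.append(
                CopyNumberSegment(sample_id, block[0], block[1], UNCHANGED, 0)
            )
            continue
        block_classes = classes[idx].copy()
        for first, last, label in _runs(block_classes):
            if label == LOSS and last - first + 1 < min_run:
                block_classes[first : last + 1] = UNCHANGED
        cursor = block[0]
        runs = _runs(block_classes)
        for r, (first, last, label) in enumerate(runs):
            if r + 1 < len(runs):
                nxt = idx[runs[r + 1][0]]
                end = int((design.ends[idx[last]] + design.starts[nxt]) // 2)
            else:
                end = block[1]
            mean_ratio = (
                float(np.mean(smoothed[idx[first] : idx[last] + 1]))
                if smoothed is not None
                else float("nan")
            )
            segments.append(
                CopyNumberSegment(
                    sample_id, cursor, end, str(label), last - first + 1, mean_ratio
                )
            )
            cursor = end
    segments.sort(key=lambda s: s.start)
    return segments


def loss_hull(
    segments: list[CopyNumberSegment], extend_through_no_call: bool = True
) -> Interval | None:
    """Extent of copy-number loss: min start to max end of loss segments.

    The hull spans interleaved no_call stretches (gap, LCR masks), matching
    how the extent of a loss region is drawn across uncallable sequence.
    With ``extend_through_no_call`` (default) the hull is additionally
    extended outward through no_call segments that directly abut it: a loss
    bounded by uncallable sequence plausibly continues into it, and its
    true edge cannot be observed there.
    """
    losses = [s for s in segments if s.cls == LOSS]
    if not losses:
        return None
    start = min(s.start for s in losses)
    end = max(s.end for s in losses)
    if extend_through_no_call:
        ordered = sorted(segments, key=lambda s: s.start)
        changed = True
        while changed:
            changed = False
            for seg in ordered:
                if seg.cls == NO_CALL and (seg.end == start or seg.start == end):
                    start = min(start, seg.start)
                    end = max(end, seg.end)
                    changed = True
    return (start, end)


def is_carrier(
    segments: list[CopyNumberSegment],
    locus: Interval,
    min_overlap_bp: int = 1,
) -> bool:
    """Carrier iff any loss segment overlaps the locus by >= min_overlap_bp."""
    return any(
        s.cls == LOSS and overlap_bp(s.interval, locus) >= min_overlap_bp
        for s in segments
    )


class ACGHCaller:
    """Reference-envelope copy-number caller (fit on normals, predict cases).

    Scikit-learn-style estimator: :meth:`fit` smooths the normal panel and
    stores the envelope as ``envelope_``; :meth:`predict` returns a boolean
    carrier verdict per sample of a case matrix, and
    :meth:`call_segments` the full segmentations.

    Parameters
    ----------
    design, region : the tiling array design and region model.
    window : moving-average window in probes (odd). 1 disables smoothing.
    min_run : minimum consecutive loss probes supporting a loss segment.
    locus : carrier-query interval; defaults to the gap plus 150-kb flanks.
    min_overlap_bp : minimum loss-segment overlap with the locus.
    """

    def __init__(
        self,
        design: ArrayDesign,
        region: RegionModel,
        window: int = 5,
        min_run: int = 30,
        locus: Interval | None = None,
        min_overlap_bp: int = 1,
    ):
        self.design = design
        self.region = region
        self.window = window
        self.min_run = min_run
        self.locus = locus
        self.min_overlap_bp = min_overlap_bp

    def _locus(self) -> Interval:
        return self.locus if self.locus is not None else default_query_locus(self.region)

    def fit(self, normal_matrix: IntensityMatrix, y=None):
        tracks = smooth_matrix(normal_matrix, self.window)
        self.envelope_ = build_envelope(tracks)
        return self

    def call_segments(
        self, matrix: IntensityMatrix
    ) -> dict[str, list[CopyNumberSegment]]:
        out = {}
        for track in smooth_matrix(matrix, self.window):
            classes = classify_probes(track, self.envelope_)
            out[track.sample_id] = segment_calls(
                classes,
                self.design,
                self.region,
                min_run=self.min_run,
                sample_id=track.sample_id,
                smoothed=track.values,
            )
        return out

    def predict(self, matrix: IntensityMatrix) -> np.ndarray:
        segs = self.call_segments(matrix)
        locus = self._locus()
        return np.array(
            [
                is_carrier(segs[sid], locus, self.min_overlap_bp)
                for sid in matrix.samples["sample_id"]
            ],
            dtype=bool,
        )


def validate_samples(
    case_matrix: IntensityMatrix,
    normal_matrix: IntensityMatrix,
    design: ArrayDesign,
    region: RegionModel,
    window: int = 5,
    min_run: int = 30,
    locus: Interval | None = None,
    min_overlap_bp: int = 1,
) -> tuple[dict[str, list[CopyNumberSegment]], pd.DataFrame]:
    """Run the full aCGH validation stage.

    Smooths every track, builds the reference envelope from the normal
    panel, classifies and segments each case sample, and returns
    (per-sample segments, verdicts DataFrame with columns sample_id,
    status, carrier).
    """
    caller = ACGHCaller(
        design,
        region,
        window=window,
        min_run=min_run,
        locus=locus,
        min_overlap_bp=min_overlap_bp,
    ).fit(normal_matrix)
    segments = caller.call_segments(case_matrix)
    verdicts = case_matrix.samples[["sample_id", "status"]].copy()
    verdicts["carrier"] = caller.predict(case_matrix)
    return segments, verdicts
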