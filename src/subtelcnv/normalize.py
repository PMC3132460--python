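"""Intensity normalization: median centering, GC-bias correction, and
PCA-based batch-effect removal.

The original platform's normalization equations are proprietary and
undisclosed; this module implements documented standard stand-ins:
per-sample median centering, a per-sample regression of log2 ratio on
probe GC fraction (closed-form linear by default, lowess optionally), and
removal of the top-k principal components estimated on probes outside any
candidate-CNV interval so true copy-number signal is not regressed out.

The two corrector classes follow the scikit-learn estimator protocol
(``fit``/``transform`` on probes x samples arrays); the module-level
functions wrap them for :class:`~subtelcnv.simulate.IntensityMatrix`
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .intervals import Interval
from .simulate import ArrayDesign, IntensityMatrix

try:  # lowess is optional: the linear method is the default
    from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess
except ImportError:  # pragma: no cover
    _lowess = None


@dataclass
class NormalizationReport:
    """What a correction did: fits, components removed, warnings."""

    gc_coefficients: dict = field(default_factory=dict)  # sample -> (a, b)
    n_components_removed: int = 0
    variance_explained: tuple = ()
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        fr = np.asarray(self.variance_explained, dtype=float)
        if fr.size and (np.any(fr < -1e-12) or np.any(fr > 1 + 1e-12)):
            raise ValueError("variance fractions must lie in [0, 1]")
        if fr.size > 1 and np.any(np.diff(fr) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")


def median_center(
    matrix: IntensityMatrix,
    design: ArrayDesign | None = None,
    exclude_intervals: list[Interval] = (),
) -> IntensityMatrix:
    """Subtract each sample's median log2 ratio (diploid baseline at 0).

    When a large CNV may cover a sizeable fraction of the probes, pass the
    candidate intervals via ``exclude_intervals`` (with ``design``): the
    median is then estimated on the remaining reference probes only, so a
    carrier's baseline is not pulled by its own deletion. The shift is
    always subtracted from every probe.
    """
    values = matrix.values.to_numpy()
    mask = np.ones(values.shape[0], dtype=bool)
    if exclude_intervals:
        if design is None:
            raise ValueError("design is required when excluding intervals")
        for iv in exclude_intervals:
            mask &= ~design.probes_in(iv)
        if not mask.any():
            raise ValueError("exclude_intervals cover every probe")
    centered = values - np.median(values[mask], axis=0, keepdims=True)
    return matrix.copy_with_values(centered)


class GCBiasCorrector(BaseEstimator, TransformerMixin):
    """Per-sample regression of log2 ratio on probe GC fraction.

    Parameters
    ----------
    gc : array of GC fractions, one per probe row.
    method : "linear" (closed-form least squares, default) or "loess"
        (lowess with fixed span).
    span : lowess span, fraction of probes in the local window.
    """

    def __init__(self, gc=None, method: str = "linear", span: float = 0.3):
        self.gc = gc
        self.method = method
        self.span = span

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be probes x samples")
        gc = np.asarray(self.gc, dtype=float)
        if gc.shape != (X.shape[0],):
            raise ValueError("gc must have one value per probe row")
        if not np.all(np.isfinite(gc)):
            raise ValueError("gc fractions must be finite")
        if self.method not in ("linear", "loess"):
            raise ValueError(f"unknown method {self.method!r}")
        self.constant_gc_ = bool(np.ptp(gc) == 0)
        self.coef_ = {}
        self.fitted_ = np.zeros_like(X)
        if self.constant_gc_:
            return self
        # only the GC-dependent part of the fit is subtracted, so a
        # GC-independent matrix passes through unchanged
        centered_gc = gc - gc.mean()
        if self.method == "linear":
            denom = float(centered_gc @ centered_gc)
            slopes = (centered_gc @ X) / denom
            self.fitted_ = np.outer(centered_gc, slopes)
            self.coef_ = {j: (0.0, float(slopes[j])) for j in range(X.shape[1])}
        else:
            if _lowess is None:  # pragma: no cover
                raise RuntimeError("statsmodels is required for method='loess'")
            for j in range(X.shape[1]):
                smooth = _lowess(X[:, j], gc, frac=self.span, return_sorted=False)
                self.fitted_[:, j] = smooth - smooth.mean()
                self.coef_[j] = ("loess", self.span)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape != self.fitted_.shape:
            raise ValueError("transform requires the matrix passed to fit")
        return X - self.fitted_


class BatchEffectRemover(BaseEstimator, TransformerMixin):
    """Remove the top-k principal components of the probes x samples matrix.

    Components (sample-space singular vectors) are estimated using only
    probe rows where ``estimation_mask`` is True, then projected out of
    every probe row. Excluding candidate-CNV probes from estimation keeps
    true deletion signal from being absorbed into a component.
    """

    def __init__(self, n_components: int = 2, estimation_mask=None):
        self.n_components = n_components
        self.estimation_mask = estimation_mask

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be probes x samples")
        k = int(self.n_components)
        self.skipped_ = k <= 0
        if self.skipped_:
            self.components_ = np.zeros((X.shape[1], 0))
            self.variance_explained_ = ()
            return self
        if k >= X.shape[1]:
            raise ValueError(
                f"n_components={k} must be smaller than the sample count "
                f"{X.shape[1]}"
            )
        mask = (
            np.ones(X.shape[0], dtype=bool)
            if self.estimation_mask is None
            else np.asarray(self.estimation_mask, dtype=bool)
        )
        if mask.shape != (X.shape[0],):
            raise ValueError("estimation_mask must have one entry per probe")
        if not mask.any():
            raise ValueError("estimation_mask excludes every probe")
        _, s, vt = np.linalg.svd(X[mask], full_matrices=False)
        total = float(np.sum(s**2))
        self.components_ = vt[:k].T  # samples x k, orthonormal columns
        self.variance_explained_ = (
            tuple((s[:k] ** 2 / total).tolist()) if total > 0 else (0.0,) * k
        )
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.skipped_:
            return X.copy()
        v = self.components_
        return X - (X @ v) @ v.T


def gc_correct(
    matrix: IntensityMatrix,
    design: ArrayDesign,
    method: str = "linear",
    span: float = 0.3,
) -> tuple[IntensityMatrix, NormalizationReport]:
    """Fit and subtract each sample's GC trend; see :class:`GCBiasCorrector`."""
    if len(design) != matrix.n_probes:
        raise ValueError("design does not match matrix probe count")
    corrector = GCBiasCorrector(gc=design.gc, method=method, span=span)
    X = matrix.values.to_numpy()
    corrected = corrector.fit(X).transform(X)
    report = NormalizationReport(
        gc_coefficients={
            matrix.samples["sample_id"].iloc[j]: coef
            for j, coef in corrector.coef_.items()
        }
    )
    if corrector.constant_gc_:
        report.warnings.append("constant GC across probes: correction skipped")
        return matrix.copy_with_values(X.copy()), report
    return matrix.copy_with_values(corrected), report


def remove_batch_pca(
    matrix: IntensityMatrix,
    k: int = 2,
    exclude_intervals: list[Interval] = (),
    design: ArrayDesign | None = None,
) -> tuple[IntensityMatrix, NormalizationReport]:
    """Project the top-k principal components out of every probe row.

    ``exclude_intervals`` (with ``design`` supplying probe coordinates)
    removes candidate-CNV probes from component estimation only; the
    projection is still applied to all probes.
    """
    mask = None
    if exclude_intervals:
        if design is None:
            raise ValueError("design is required when excluding intervals")
        mask = np.ones(len(design), dtype=bool)
        for iv in exclude_intervals:
            mask &= ~design.probes_in(iv)
    remover = BatchEffectRemover(n_components=k, estimation_mask=mask)
    X = matrix.values.to_numpy()
    corrected = remover.fit(X).transform(X)
    report = NormalizationReport(
        n_components_removed=0 if remover.skipped_ else int(k),
        variance_explained=remover.variance_explained_,
    )
    if remover.skipped_:
        report.warnings.append("k <= 0: batch removal skipped (identity)")
    return matrix.copy_with_values(corrected), report
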