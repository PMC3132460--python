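"""Stage-1 genome-screening caller for the sparse BeadChip-style design.

Per candidate locus, samples are summarized by their mean log2 ratio over
the locus probes and clustered with a one-dimensional Gaussian mixture
(EM, quantile-based initialization, model order chosen by BIC over
k in {1, 2, 3}). Components are mapped to copy-number classes by their
means: a component within ``min_separation`` of zero is "unchanged", a
lower one is "loss", a higher one is "gain". Evidence for a CNV requires
more than one consecutive probe showing the abnormality (the consecutive
run constraint), and a candidate is "reliable" only if it spans at least
50 kb over at least 50 consecutive probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .intervals import Interval
from .simulate import ArrayDesign, IntensityMatrix

LOSS, UNCHANGED, GAIN = "loss", "unchanged", "gain"

_INIT_QUANTILES = {1: (0.5,), 2: (0.1, 0.9), 3: (0.1, 0.5, 0.9)}
_VAR_FLOOR = 1e-8


def summarize_locus(
    matrix: IntensityMatrix, design: ArrayDesign, locus: Interval
) -> np.ndarray:
    """Per-sample mean log2 ratio over probes with midpoint inside ``locus``."""
    if len(design) != matrix.n_probes:
        raise ValueError("design does not match matrix probe count")
    mask = design.probes_in(locus)
    if not mask.any():
        raise ValueError(
            f"no probes overlap locus [{locus[0]:,}, {locus[1]:,}) "
            "(probe-free gap?)"
        )
    return matrix.values.to_numpy()[mask].mean(axis=0)


def _em_1d(x, k, max_iter, tol):
    """EM for a 1-D Gaussian mixture; returns params and loglik trace."""
    n = x.size
    means = np.quantile(x, _INIT_QUANTILES[k]).astype(float)
    variances = np.full(k, max(np.var(x), _VAR_FLOOR))
    weights = np.full(k, 1.0 / k)
    trace = []
    converged = False
    for _ in range(max_iter):
        # E step: log responsibilities
        log_comp = (
            np.log(weights)[None, :]
            - 0.5 * np.log(2 * np.pi * variances)[None, :]
            - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
        )
        log_norm = np.logaddexp.reduce(log_comp, axis=1)
        loglik = float(log_norm.sum())
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        resp = np.exp(log_comp - log_norm[:, None])
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, _VAR_FLOOR)
    return weights, means, variances, trace, converged


class GaussianMixtureScreen(BaseEstimator):
    """1-D Gaussian-mixture classifier of per-sample locus summaries.

    Follows the scikit-learn estimator protocol: :meth:`fit` selects the
    mixture order by BIC and :meth:`predict` returns a copy-number class
    per value. Quantile initialization makes the fit deterministic and
    invariant to permutations of the input; ``random_state`` is accepted
    for interface compatibility.

    Attributes (after fit): ``k_``, ``weights_``, ``means_``,
    ``variances_``, ``bic_`` (dict k -> BIC), ``loglik_trace_``,
    ``converged_``, ``class_map_`` (component index -> class label).
    """

    def __init__(
        self,
        max_k: int = 3,
        min_separation: float = 0.3,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.max_k = max_k
        self.min_separation = min_separation
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 10:
            raise ValueError(f"need at least 10 values to cluster, got {x.size}")
        if not 1 <= self.max_k <= 3:
            raise ValueError("max_k must be in {1, 2, 3}")
        self.bic_ = {}
        fits = {}
        for k in range(1, self.max_k + 1):
            w, m, v, trace, conv = _em_1d(x, k, self.max_iter, self.tol)
            n_params = 3 * k - 1
            self.bic_[k] = -2.0 * trace[-1] + n_params * np.log(x.size)
            fits[k] = (w, m, v, trace, conv)
        self.k_ = min(self.bic_, key=self.bic_.get)
        w, m, v, trace, conv = fits[self.k_]
        self.weights_, self.means_, self.variances_ = w, m, v
        self.loglik_trace_ = trace
        self.converged_ = conv
        self.class_map_ = {}
        for i, mean in enumerate(m):
            if abs(mean) <= self.min_separation:
                self.class_map_[i] = UNCHANGED
            elif mean < 0:
                self.class_map_[i] = LOSS
            else:
                self.class_map_[i] = GAIN
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).ravel()
        if not self.converged_:
            # flagged model: no call is made, everything is unchanged
            return np.array([UNCHANGED] * x.size, dtype=object)
        log_comp = (
            np.log(self.weights_)[None, :]
            - 0.5 * np.log(2 * np.pi * self.variances_)[None, :]
            - 0.5 * (x[:, None] - self.means_[None, :]) ** 2
            / self.variances_[None, :]
        )
        comp = np.argmax(log_comp, axis=1)
        return np.array([self.class_map_[int(c)] for c in comp], dtype=object)


@dataclass
class ClusterModel:
    """Fitted mixture plus the per-sample class assignment."""

    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    bic: dict
    class_map: dict
    converged: bool
    classes: np.ndarray
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self):
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("mixture variances must be positive")


def fit_gmm_classes(
    values,
    max_k: int = 3,
    seed: int | None = None,
    min_separation: float = 0.3,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ClusterModel:
    """Cluster per-sample summaries into copy-number classes; see
    :class:`GaussianMixtureScreen`."""
    est = GaussianMixtureScreen(
        max_k=max_k,
        min_separation=min_separation,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(values)
    return ClusterModel(
        k=est.k_,
        weights=est.weights_,
        means=est.means_,
        variances=est.variances_,
        bic=est.bic_,
        class_map=est.class_map_,
        converged=est.converged_,
        classes=est.predict(values),
        loglik_trace=est.loglik_trace_,
    )


def apply_consecutive_constraint(
    classes, design: ArrayDesign, min_run: int = 2
) -> list[Interval]:
    """Turn per-probe classes into loss intervals.

    Maximal runs of at least ``min_run`` consecutive loss-classed probes
    become intervals spanning the first probe's start to the last probe's
    end; shorter runs are discarded as insufficient evidence.
    """
    classes = np.asarray(classes, dtype=object)
    if classes.shape != (len(design),):
        raise ValueError("classes must align with design probes")
    out: list[Interval] = []
    run_start = None
    for i in range(len(classes) + 1):
        is_loss = i < len(classes) and classes[i] == LOSS
        if is_loss and run_start is None:
            run_start = i
        elif not is_loss and run_start is not None:
            if i - run_start >= min_run:
                out.append(
                    (int(design.starts[run_start]), int(design.ends[i - 1]))
                )
            run_start = None
    return out


@dataclass
class CandidateCNV:
    """A candidate locus with its per-sample classes and screen verdict."""

    locus: Interval
    n_probes: int
    span_bp: int
    sample_classes: dict  # sample_id -> class
    case_losses: int
    control_losses: int
    passed_screen: bool = False

    def __post_init__(self):
        if self.span_bp != self.locus[1] - self.locus[0]:
            raise ValueError("span_bp must equal the locus length")


def screen_candidates(
    candidates: list[CandidateCNV],
    min_probes: int = 50,
    min_span: int = 50_000,
) -> list[CandidateCNV]:
    """Keep reliable candidates: >= min_probes probes over >= min_span bp."""
    passing = []
    for cand in candidates:
        cand.passed_screen = (
            cand.n_probes >= min_probes and cand.span_bp >= min_span
        )
        if cand.passed_screen:
            passing.append(cand)
    return passing


def call_locus(
    matrix: IntensityMatrix,
    design: ArrayDesign,
    locus: Interval,
    max_k: int = 3,
    seed: int | None = None,
    min_separation: float = 0.3,
) -> CandidateCNV:
    """Summarize, cluster and tabulate one candidate locus."""
    summaries = summarize_locus(matrix, design, locus)
    model = fit_gmm_classes(
        summaries, max_k=max_k, seed=seed, min_separation=min_separation
    )
    sample_ids = list(matrix.samples["sample_id"])
    status = dict(zip(matrix.samples["sample_id"], matrix.samples["status"]))
    sample_classes = dict(zip(sample_ids, model.classes))
    case_losses = sum(
        1 for s in sample_ids if status[s] == "case" and sample_classes[s] == LOSS
    )
    control_losses = sum(
        1
        for s in sample_ids
        if status[s] == "control" and sample_classes[s] == LOSS
    )
    n_probes = int(design.probes_in(locus).sum())
    return CandidateCNV(
        locus=tuple(locus),
        n_probes=n_probes,
        span_bp=locus[1] - locus[0],
        sample_classes=sample_classes,
        case_losses=case_losses,
        control_losses=control_losses,
    )
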