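"""Case-control carrier association.

A locus's carrier verdicts are cross-tabulated against case/control
status into a 2x2 table, tested with a two-sided Fisher's exact test
(full hypergeometric enumeration over all tables with the observed
margins; two-sided p = sum of point probabilities no larger than the
observed one), Bonferroni-corrected over the loci tested, and summarized
by the cross-product odds ratio with a Woolf (logit) 95% confidence
interval, applying the Haldane-Anscombe +0.5 correction when any cell
is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .intervals import Interval

#: relative tolerance when comparing point probabilities for ties
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: a/b case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row1, row2, col1, col2) totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def require_positive_margins(self) -> None:
        """Both groups must be non-empty (zero carrier columns are fine:
        a zero column collapses the enumeration to a single table, p = 1)."""
        r1, r2, _, _ = self.margins
        if r1 <= 0 or r2 <= 0:
            raise ValueError(
                f"table {self} has an empty group; the test is undefined"
            )

    def transpose_groups(self) -> "ContingencyTable":
        """Swap case and control rows."""
        return ContingencyTable(self.c, self.d, self.a, self.b)


def _log_hypergeom_pmf(a: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(A = a) for the central hypergeometric with margins (r1, r2, c1)."""
    n = r1 + r2
    c2 = n - c1
    return (
        gammaln(r1 + 1)
        - gammaln(a + 1)
        - gammaln(r1 - a + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - a + 1)
        - gammaln(r2 - c1 + a + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(c2 + 1))
    )


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p by enumeration.

    Enumerates every table with the observed margins and sums the point
    probabilities that do not exceed the observed one (with relative
    tolerance ``TIE_RTOL`` for ties), in log-factorial arithmetic.
    """
    table.require_positive_margins()
    r1, r2, c1, _ = table.margins
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    log_pmf = _log_hypergeom_pmf(support, r1, r2, c1)
    log_obs = _log_hypergeom_pmf(np.array([table.a]), r1, r2, c1)[0]
    include = log_pmf <= log_obs + np.log1p(TIE_RTOL)
    p = float(np.exp(log_pmf[include]).sum())
    return min(p, 1.0)


def odds_ratio_ci(
    table: ContingencyTable, alpha: float = 0.05
) -> tuple[float, tuple[float, float], str]:
    """Cross-product odds ratio with a Woolf (logit) confidence interval.

    Returns (point estimate, (low, high), method string). With any zero
    cell the Haldane-Anscombe +0.5 correction is applied to every cell for
    both the point estimate and the interval.
    """
    table.require_positive_margins()
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    method = "woolf"
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "woolf+haldane"
    or_point = (a * d) / (b * c)
    z = norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_or = np.log(or_point)
    ci = (float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se)))
    return float(or_point), ci, method


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni family-wise adjustment: p -> min(1, m * p)."""
    ps = [float(p) for p in p_values]
    if any(not 0.0 <= p <= 1.0 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < len(ps):
        raise ValueError(
            f"m={m} is smaller than the number of tests {len(ps)}: "
            "under-correction is not allowed"
        )
    return [min(1.0, m * p) for p in ps]


def build_table(verdicts, sample_sheet: pd.DataFrame) -> ContingencyTable:
    """Cross-tabulate per-sample carrier booleans against case/control status.

    ``verdicts`` maps sample_id -> bool (or is a DataFrame with sample_id
    and carrier columns); every sample must appear in the sheet.
    """
    if isinstance(verdicts, pd.DataFrame):
        verdicts = dict(zip(verdicts["sample_id"], verdicts["carrier"]))
    status = dict(zip(sample_sheet["sample_id"], sample_sheet["status"]))
    counts = {("case", True): 0, ("case", False): 0,
              ("control", True): 0, ("control", False): 0}
    for sid, carrier in verdicts.items():
        if sid not in status:
            raise ValueError(f"sample {sid!r} missing from the sample sheet")
        counts[(status[sid], bool(carrier))] += 1
    return ContingencyTable(
        counts[("case", True)],
        counts[("case", False)],
        counts[("control", True)],
        counts[("control", False)],
    )


@dataclass
class AssociationResult:
    """Association of carrier status with case status at one locus."""

    locus: Interval
    table: ContingencyTable
    p: float
    m: int
    p_bonferroni: float
    or_point: float
    or_ci: tuple[float, float]
    ci_method: str

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.p_bonferroni < self.p - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")


def associate_loci(
    locus_verdicts: dict[Interval, object],
    sample_sheet: pd.DataFrame,
    m_override: int | None = None,
) -> list[AssociationResult]:
    """Test every locus and Bonferroni-correct over the loci tested.

    ``locus_verdicts`` maps a locus interval to its per-sample carrier
    verdicts (mapping or DataFrame as in :func:`build_table`). ``m``
    defaults to the number of loci; ``m_override`` may only enlarge it.
    Results are sorted by raw p.
    """
    if not locus_verdicts:
        raise ValueError("at least one locus is required")
    loci = list(locus_verdicts)
    tables = {loc: build_table(locus_verdicts[loc], sample_sheet) for loc in loci}
    ps = {loc: fisher_exact_two_sided(tables[loc]) for loc in loci}
    adjusted = bonferroni([ps[loc] for loc in loci], m=m_override)
    m = m_override if m_override is not None else len(loci)
    results = []
    for loc, p_adj in zip(loci, adjusted):
        or_point, ci, method = odds_ratio_ci(tables[loc])
        results.append(
            AssociationResult(
                locus=tuple(loc),
                table=tables[loc],
                p=ps[loc],
                m=m,
                p_bonferroni=p_adj,
                or_point=or_point,
                or_ci=ci,
                ci_method=method,
            )
        )
    results.sort(key=lambda r: r.p)
    return results
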