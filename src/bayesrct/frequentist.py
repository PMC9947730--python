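"""Classical estimators for a two-arm binary outcome.

Risk difference with a Wald interval, risk ratio with the Katz log
interval, odds ratio with the Woolf log interval, and the stratified
two-sided Mantel-Haenszel chi-square test.  The 2x2 machinery is provided
by :mod:`statsmodels.stats.contingency_tables`; zero cells receive the
Haldane-Anscombe 0.5 correction (flagged in the result) before delegation.

Counts may be non-integer: the publication prints rates rather than counts
for the 30-day endpoint, and "effective counts" ``rate * n`` reproduce its
rate-based point estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import (
    StratifiedTable as _SmStratifiedTable,
    Table2x2 as _SmTable2x2,
)

from bayesrct.trial_data import StratifiedTable


class EstimateError(ValueError):
    """The requested estimate is undefined for the given counts."""


class EstimateCI(NamedTuple):
    """Point estimate with a two-sided confidence interval."""

    estimate: float
    lower: float
    upper: float
    corrected: bool = False  # True if a 0.5 zero-cell correction was applied


@dataclass(frozen=True)
class MantelHaenszelResult:
    chi2: float
    p_value: float
    n_strata_used: int


@dataclass(frozen=True)
class FrequentistResult:
    """All classical summaries for one endpoint."""

    endpoint: str
    rate_treatment: float
    rate_control: float
    risk_difference: EstimateCI
    risk_ratio: EstimateCI
    odds_ratio: EstimateCI
    mh_chi2: float
    p_value: float


def _zq(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise EstimateError("confidence level must lie in (0, 1)")
    return float(stats.norm.ppf((1.0 + level) / 2.0))


def risk_difference(
    a: float, n1: float, c: float, n2: float, level: float = 0.95
) -> EstimateCI:
    """p1 - p2 with the Wald interval ``point +- z * sqrt(Sum p q / n)``."""
    if n1 <= 0 or n2 <= 0:
        raise EstimateError("both arms must be nonempty")
    if not (0 <= a <= n1 and 0 <= c <= n2):
        raise EstimateError("deaths must lie within [0, n] per arm")
    p1, p2 = a / n1, c / n2
    point = p1 - p2
    half = _zq(level) * np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    return EstimateCI(point, point - half, point + half)


def risk_ratio(
    a: float, n1: float, c: float, n2: float, level: float = 0.95
) -> EstimateCI:
    """(p1/p2) with the Katz log interval.

    A zero death count in either arm triggers the 0.5 continuity correction
    on all four cells; both arms at zero leaves the ratio undefined.
    """
    if n1 <= 0 or n2 <= 0:
        raise EstimateError("both arms must be nonempty")
    if a == 0 and c == 0:
        raise EstimateError("risk ratio undefined: no deaths in either arm")
    corrected = a == 0 or c == 0
    if corrected:
        a, c = a + 0.5, c + 0.5
        n1, n2 = n1 + 1.0, n2 + 1.0
    table = _SmTable2x2(
        np.array([[a, n1 - a], [c, n2 - c]], dtype=float), shift_zeros=False
    )
    lo, hi = table.riskratio_confint(alpha=1.0 - level)
    return EstimateCI(float(table.riskratio), float(lo), float(hi), corrected)


def odds_ratio(
    a: float, b: float, c: float, d: float, level: float = 0.95
) -> EstimateCI:
    """ad/(bc) with the Woolf log interval; 0.5 correction for zero cells."""
    if min(a, b, c, d) < 0:
        raise EstimateError("cells must be nonnegative")
    if (a == 0 and c == 0) or (b == 0 and d == 0) or (a == 0 and b == 0) or (c == 0 and d == 0):
        raise EstimateError("odds ratio undefined: empty row or column")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    table = _SmTable2x2(np.array([[a, b], [c, d]], dtype=float), shift_zeros=False)
    lo, hi = table.oddsratio_confint(alpha=1.0 - level)
    return EstimateCI(float(table.oddsratio), float(lo), float(hi), corrected)


def _stratum_degenerate(s) -> bool:
    row1, row2 = s.a + s.b, s.c + s.d
    col1, col2 = s.a + s.c, s.b + s.d
    return min(row1, row2, col1, col2) == 0


def mantel_haenszel_test(table: StratifiedTable) -> MantelHaenszelResult:
    """Two-sided Mantel-Haenszel chi-square (no continuity correction).

    Strata with an empty margin carry no information and are dropped with a
    warning; the statistic uses the standard hypergeometric mean/variance
    per stratum and is referred to a chi-square with 1 df.
    """
    usable = [s for s in table.strata if not _stratum_degenerate(s)]
    dropped = len(table.strata) - len(usable)
    if dropped:
        warnings.warn(
            f"dropped {dropped} degenerate stratum/strata with an empty margin",
            stacklevel=2,
        )
    if not usable:
        raise EstimateError("all strata are degenerate")
    arrays = [np.array([[s.a, s.b], [s.c, s.d]], dtype=float) for s in usable]
    res = _SmStratifiedTable(arrays).test_null_odds(correction=False)
    return MantelHaenszelResult(float(res.statistic), float(res.pvalue), len(usable))


def analyze_counts(
    endpoint: str,
    a: float,
    n1: float,
    c: float,
    n2: float,
    level: float = 0.95,
    table: StratifiedTable | None = None,
) -> FrequentistResult:
    """Bundle all classical summaries for one endpoint.

    The Mantel-Haenszel test uses ``table`` when given (the stratified
    analysis); otherwise the pooled 2x2 forms a single stratum.
    """
    if table is None:
        from bayesrct.trial_data import stratified_from_counts

        table = stratified_from_counts(endpoint, int(a), int(n1), int(c), int(n2))
    mh = mantel_haenszel_test(table)
    return FrequentistResult(
        endpoint=endpoint,
        rate_treatment=a / n1,
        rate_control=c / n2,
        risk_difference=risk_difference(a, n1, c, n2, level),
        risk_ratio=risk_ratio(a, n1, c, n2, level),
        odds_ratio=odds_ratio(a, n1 - a, c, n2 - c, level),
        mh_chi2=mh.chi2,
        p_value=mh.p_value,
    )


def rates_based_comparison(
    rate1: float, n1: int, rate2: float, n2: int, level: float = 0.95
) -> tuple[EstimateCI, EstimateCI]:
    """Risk difference and risk ratio computed from printed rates.

    Uses effective (non-integer) counts ``rate * n``; this is the path that
    reproduces the published 30-day point estimates, whose printed rates are
    not consistent with any integer death count over the arm sizes.
    """
    a, c = rate1 * n1, rate2 * n2
    return (
        risk_difference(a, n1, c, n2, level),
        risk_ratio(a, n1, c, n2, level),
    )
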