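"""Estimators for the burden analysis.

* binomial prevalence with a 95% CI — Wald (normal approximation) by
  default, switching to the Wilson score interval when the proportion is
  close enough to 0 (or 1) for the Wald interval to leave [0, 1];
* Sperrin's *I*, an index of encounter-timing regularity over a patient's
  follow-up (1 = perfectly regular visits);
* Cohen's kappa for two-reviewer agreement on a 2x2 vote table;
* tie-aware (average-rank) Spearman correlation;
* the overall burden: prevalence of "at least one panel disease".
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .errors import UndefinedStatisticError

__all__ = [
    "PrevalenceEstimate",
    "RegularityScore",
    "AgreementTable",
    "RankCorrelation",
    "Z_DEFAULT",
    "prevalence_ci",
    "sperrin_I",
    "cohens_kappa",
    "spearman_rho",
    "burden_summary",
    "round_half_up",
]

Z_DEFAULT = 1.959964  # two-sided 95%


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (report convention)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A per-1000 prevalence with its CI and the interval method used."""

    dui: str
    n_cases: int
    n_total: int
    p_per_1000: float
    ci_low_per_1000: float
    ci_high_per_1000: float
    method: str  # "normal" | "wilson"

    def rounded(self) -> tuple[float, float, float]:
        """(point, low, high) per 1000, one decimal, half-up."""
        return (
            round_half_up(self.p_per_1000),
            round_half_up(self.ci_low_per_1000),
            round_half_up(self.ci_high_per_1000),
        )


def prevalence_ci(
    n_cases: int,
    n_total: int,
    alpha: float = 0.05,
    dui: str = "",
    z: float | None = None,
) -> PrevalenceEstimate:
    """Binomial prevalence per 1000 with the method-selection rule.

    The Wald interval ``p ± z·sqrt(p(1-p)/n)`` is used unless it would
    leave [0, 1] (including the degenerate zero-successes case, whose Wald
    interval collapses to [0, 0]); then the Wilson score interval is used
    instead.  This operationalizes "Wilson's interval if the proportion is
    close to 0%": every reported lower bound is ≥ 0.
    """
    if n_total < 1:
        raise UndefinedStatisticError("prevalence undefined for an empty cohort")
    if not 0 <= n_cases <= n_total:
        raise ValueError(f"n_cases={n_cases} outside [0, {n_total}]")
    if z is None:
        z = Z_DEFAULT if alpha == 0.05 else float(sps.norm.ppf(1 - alpha / 2))
    p = n_cases / n_total
    se = math.sqrt(p * (1 - p) / n_total)
    wald_low, wald_high = p - z * se, p + z * se
    if n_cases == 0 or wald_low < 0 or wald_high > 1:
        low, high = proportion_confint(n_cases, n_total, alpha=alpha, method="wilson")
        # float fuzz: Wilson bounds are exact at the boundary cases
        if n_cases == 0:
            low = 0.0
        if n_cases == n_total:
            high = 1.0
        method = "wilson"
    else:
        low, high = wald_low, wald_high
        method = "normal"
    return PrevalenceEstimate(
        dui=dui,
        n_cases=int(n_cases),
        n_total=int(n_total),
        p_per_1000=1000.0 * p,
        ci_low_per_1000=1000.0 * low,
        ci_high_per_1000=1000.0 * high,
        method=method,
    )


@dataclass(frozen=True)
class RegularityScore:
    patient_id: str
    n_encounters: int
    I: float


def sperrin_I(
    encounter_dates: Sequence[dt.date | dt.datetime | float],
    patient_id: str = "",
) -> RegularityScore:
    """Encounter-timing regularity index.

    With n encounters spanning a follow-up period, the n-1 inter-encounter
    gaps are normalized to fractions of the span (they sum to 1) and

        I = 2/n + ((n-2)/n) * [1 - sqrt((n-1) * Var(g_1..g_{n-1}))]

    where Var is the population (mean-squared-deviation) variance of the
    normalized gaps.  Equal spacing gives Var = 0, hence I = 1; so does
    n = 2, where the (n-2)/n coefficient vanishes.  The result is clamped
    to [0, 1].  Undefined (signaled) for fewer than 2 distinct dates or a
    zero span.
    """
    vals = sorted(
        float(d.toordinal()) if isinstance(d, (dt.date, dt.datetime)) else float(d)
        for d in encounter_dates
    )
    n = len(vals)
    if n < 2:
        raise UndefinedStatisticError("regularity needs at least 2 encounters")
    span = vals[-1] - vals[0]
    if span <= 0:
        raise UndefinedStatisticError("regularity undefined for zero follow-up span")
    gaps = np.diff(vals) / span
    var = float(np.var(gaps))  # population variance over the n-1 gaps
    value = 2.0 / n + (n - 2) / n * (1.0 - math.sqrt((n - 1) * var))
    return RegularityScore(patient_id=patient_id, n_encounters=n, I=min(1.0, max(0.0, value)))


@dataclass(frozen=True)
class AgreementTable:
    """2x2 two-reviewer vote table."""

    n_both_approve: int
    n_both_reject: int
    n_disagree_ab: int  # reviewer A approves, B rejects
    n_disagree_ba: int  # reviewer A rejects, B approves

    def __post_init__(self) -> None:
        cells = (self.n_both_approve, self.n_both_reject, self.n_disagree_ab, self.n_disagree_ba)
        if any(c < 0 for c in cells):
            raise ValueError("vote counts must be non-negative")
        if sum(cells) == 0:
            raise UndefinedStatisticError("agreement undefined for an empty vote table")

    @property
    def total(self) -> int:
        return self.n_both_approve + self.n_both_reject + self.n_disagree_ab + self.n_disagree_ba

    def transposed(self) -> "AgreementTable":
        return AgreementTable(
            self.n_both_approve, self.n_both_reject, self.n_disagree_ba, self.n_disagree_ab
        )


def cohens_kappa(table: AgreementTable) -> float:
    """Chance-corrected two-rater agreement from a 2x2 table."""
    from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

    n = table.total
    a, d = table.n_both_approve, table.n_both_reject
    b, c = table.n_disagree_ab, table.n_disagree_ba
    p_a = (a + b) / n
    p_b = (a + c) / n
    pe = p_a * p_b + (1 - p_a) * (1 - p_b)
    if pe >= 1.0:
        raise UndefinedStatisticError("kappa undefined: expected agreement is 1 (degenerate marginals)")
    res = _sm_kappa(np.array([[a, b], [c, d]]), return_results=False)
    return float(res)


@dataclass(frozen=True)
class RankCorrelation:
    rho: float
    n: int
    tie_method: str = "average"


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> RankCorrelation:
    """Spearman correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise UndefinedStatisticError("rank correlation needs at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("rank correlation undefined for a constant vector")
    rho = float(sps.spearmanr(x, y).statistic)
    return RankCorrelation(rho=rho, n=len(x))


def burden_summary(calls, alpha: float = 0.05) -> PrevalenceEstimate:
    """Prevalence of "at least one panel disease present" over the cohort.

    *calls* is an iterable of phenotype calls (anything with ``patient_id``
    and ``present`` attributes) covering the full cohort x panel grid.
    """
    patients: set[str] = set()
    burdened: set[str] = set()
    for c in calls:
        patients.add(c.patient_id)
        if c.present:
            burdened.add(c.patient_id)
    if not patients:
        raise UndefinedStatisticError("no calls supplied")
    return prevalence_ci(len(burdened), len(patients), alpha=alpha, dui="ANY")
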