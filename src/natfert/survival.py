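"""Nonparametric survival comparison of time from marriage to the kth birth.

Men with fewer than k births contribute censored observations at the time
of their last birth.  Curves are Kaplan–Meier product-limit estimates
(events precede censorings at tied times); groups are compared by the
log-rank test, and completed family sizes by the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .phenotypes import ExcludedRecord, ReproductiveHistory

__all__ = [
    "SurvivalRecord",
    "SurvivalCurve",
    "LogRankResult",
    "time_to_kth_birth",
    "kaplan_meier",
    "log_rank",
    "wilcoxon_rank_sum",
    "cumulative_birth_summary",
    "married_at_least",
]


@dataclass(frozen=True)
class SurvivalRecord:
    individual_id: str
    time: float  # years from marriage
    event: bool  # True = reached the kth birth, False = censored
    group: str = ""


@dataclass
class SurvivalCurve:
    """Product-limit estimate with its risk table."""

    times: np.ndarray  # distinct observed times (events and censorings)
    n_risk: np.ndarray
    n_event: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray  # S(t) just after each time

    def at(self, t: float) -> float:
        """S(t); 1 before the first observed time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]


def time_to_kth_birth(history: ReproductiveHistory, k: int) -> SurvivalRecord:
    """Event time to the kth birth, censored at the last birth if < k births."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ys = history.birth_years
    if not ys:
        raise ExcludedRecord(f"{history.individual_id}: no births")
    if len(ys) >= k:
        return SurvivalRecord(
            history.individual_id, ys[k - 1] - history.marriage_year, True
        )
    return SurvivalRecord(
        history.individual_id, ys[-1] - history.marriage_year, False
    )


def kaplan_meier(records: Sequence[SurvivalRecord]) -> SurvivalCurve:
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter().fit(times, events)
    tab = kmf.event_table
    tab = tab[tab["removed"] > 0]  # drop lifelines' synthetic t=0 row
    t = tab.index.to_numpy(dtype=float)
    surv = np.array([kmf.predict(x) for x in t], dtype=float)
    return SurvivalCurve(
        times=t,
        n_risk=tab["at_risk"].to_numpy(dtype=int),
        n_event=tab["observed"].to_numpy(dtype=int),
        n_censored=tab["censored"].to_numpy(dtype=int),
        survival=surv,
    )


def _oe_table(times, events, groups):
    """Observed and expected event counts per group (hypergeometric E)."""
    labels = sorted(set(groups))
    obs = {g: 0.0 for g in labels}
    exp = {g: 0.0 for g in labels}
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    for t in np.unique(times[events]):
        at_risk = times >= t
        d = events & (times == t)
        n_t, d_t = at_risk.sum(), d.sum()
        for g in labels:
            ing = groups == g
            obs[g] += float((d & ing).sum())
            exp[g] += d_t * float((at_risk & ing).sum()) / n_t
    return obs, exp


def log_rank(records: Sequence[SurvivalRecord]) -> LogRankResult:
    """Log-rank comparison across the groups present in ``records``.

    Chi-square and p come from the standard multigroup statistic with the
    full hypergeometric covariance (df = groups - 1); the per-group
    observed/expected table satisfies sum(O - E) = 0.
    """
    groups = [r.group for r in records]
    labels = sorted(set(groups))
    if len(labels) < 2:
        raise ValueError("log-rank needs at least two groups")
    times = [r.time for r in records]
    events = [r.event for r in records]
    for g in labels:
        if not any(r.group == g for r in records):
            raise ValueError(f"group {g} has no records")
    res = multivariate_logrank_test(times, groups, events)
    obs, exp = _oe_table(times, events, groups)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=len(labels) - 1,
        p_value=float(res.p_value),
        observed=obs,
        expected=exp,
    )


def wilcoxon_rank_sum(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    alternative: str = "two-sided",
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney U) of two samples.

    Exact enumeration when the combined sample size is <= ``exact_max_n``
    and there are no ties; tie-corrected normal approximation otherwise.
    Returns (U statistic for the first sample, p-value).
    """
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (a.size + b.size <= exact_max_n and no_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def cumulative_birth_summary(
    histories_by_group: Mapping[str, Iterable[ReproductiveHistory]],
    max_birth: int,
) -> pd.DataFrame:
    """Mean (and SE) years from marriage to each birth order, per group.

    For birth order b, only men with >= b births contribute.  SE is the
    standard error of the mean; reported as 0 with ``se_defined = False``
    when fewer than two men contribute.
    """
    rows = []
    for group, histories in histories_by_group.items():
        histories = list(histories)
        for b in range(1, max_birth + 1):
            waits = [
                h.birth_years[b - 1] - h.marriage_year
                for h in histories
                if len(h.birth_years) >= b
            ]
            if not waits:
                continue
            arr = np.asarray(waits, float)
            se_defined = arr.size >= 2
            rows.append(
                {
                    "group": group,
                    "birth_order": b,
                    "n": arr.size,
                    "mean_years": float(arr.mean()),
                    "se_years": float(arr.std(ddof=1) / np.sqrt(arr.size))
                    if se_defined else 0.0,
                    "se_defined": se_defined,
                }
            )
    return pd.DataFrame(rows)


def married_at_least(
    histories: Sequence[ReproductiveHistory], threshold: float | None = None
) -> tuple[list[ReproductiveHistory], float]:
    """Filter to men married at least ``threshold`` years.

    When ``threshold`` is None it is recomputed as the sample mean of the
    marriage-to-last-birth span (the cohort's own average reproductive
    period), and the threshold actually used is returned.
    """
    if threshold is None:
        spans = [h.marriage_to_last_birth for h in histories if h.birth_years]
        threshold = float(np.mean(spans))
    kept = [h for h in histories
            if h.observation_end - h.marriage_year >= threshold]
    return kept, threshold
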