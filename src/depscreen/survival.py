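"""Median-split stratification, Kaplan-Meier estimation and the Mantel-Cox
log-rank test.

A cohort is split at the median of a covariate (typically one gene's
transcript level or z-score) into "low" and "high" strata; overall survival
is then compared with the product-limit estimator and the two-group
log-rank statistic

    chi2 = (O_A - E_A)^2 / V,   1 df,

where O_A and E_A are observed and expected event totals in one group
summed over distinct event times, and V is the hypergeometric variance
contribution at each event time.  Subjects censored at an event time are
counted as still at risk for that time (events-before-censoring
convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import welch_t_test
from .io import ClinicalTable

__all__ = [
    "StratifiedCohort",
    "KMEstimate",
    "LogRankResult",
    "stratify_by_median",
    "km_estimate",
    "logrank_test",
    "compare_expression_between_strata",
    "survival_analysis",
]


@dataclass
class StratifiedCohort:
    """Low/high stratum label per sample and the median used to split."""

    samples: list[str]
    labels: pd.Series  # index: sample id, values in {"low", "high"}
    split_value: float

    @property
    def low(self) -> list[str]:
        return [s for s in self.samples if self.labels[s] == "low"]

    @property
    def high(self) -> list[str]:
        return [s for s in self.samples if self.labels[s] == "high"]


def stratify_by_median(
    values: pd.Series | dict, tie_policy: str = "low"
) -> StratifiedCohort:
    """Split samples at the median of a covariate.

    The median is the mean of the two central order statistics for even
    sizes.  Values strictly below go to "low", strictly above to "high";
    values exactly at the median follow ``tie_policy`` ("low" by default).
    All-identical values cannot be stratified and raise.
    """
    values = pd.Series(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 samples to stratify")
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("covariate values must be finite")
    if tie_policy not in ("low", "high"):
        raise ValueError(f"tie_policy must be 'low' or 'high', got {tie_policy!r}")
    med = float(np.median(values.to_numpy()))
    if values.nunique() == 1:
        raise ValueError("all covariate values identical; cannot stratify")
    if tie_policy == "low":
        labels = pd.Series(np.where(values > med, "high", "low"), index=values.index)
    else:
        labels = pd.Series(np.where(values >= med, "high", "low"), index=values.index)
    return StratifiedCohort(
        samples=list(values.index), labels=labels, split_value=med
    )


@dataclass
class KMEstimate:
    """Product-limit survival estimate over the distinct event times."""

    event_times: np.ndarray
    n_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): survival probability just after time t (S(0) = 1)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_risk": self.n_risk,
                "n_event": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("events must be 0 or 1")

    event_times = np.unique(times[events == 1])
    n_risk = np.empty(event_times.size)
    n_events = np.empty(event_times.size)
    for j, t in enumerate(event_times):
        n_risk[j] = np.sum(times >= t)  # censored at t still at risk for t
        n_events[j] = np.sum((times == t) & (events == 1))
    with np.errstate(invalid="ignore"):
        survival = np.cumprod(1.0 - n_events / n_risk)
    return KMEstimate(
        event_times=event_times,
        n_risk=n_risk.astype(int),
        n_events=n_events.astype(int),
        survival=survival,
    )


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    observed: dict[str, float]
    expected: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        groups = list(self.observed)
        return pd.DataFrame(
            {
                "group": groups,
                "observed": [self.observed[g] for g in groups],
                "expected": [self.expected[g] for g in groups],
                "chi_square": self.chi_square,
                "p_value": self.p_value,
            }
        )


def logrank_test(groups, times, events) -> LogRankResult:
    """Two-group Mantel-Cox log-rank test.

    ``groups`` is either a StratifiedCohort or a per-subject label
    sequence aligned with ``times``/``events``; exactly two distinct
    labels are required.  When the variance term is zero (no comparative
    information, e.g. a single subject) the test degenerates to chi2 0,
    p 1 with a warning.
    """
    if isinstance(groups, StratifiedCohort):
        labels = np.asarray([groups.labels[s] for s in groups.samples])
    else:
        labels = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if labels.shape[0] != times.shape[0] or times.shape[0] != events.shape[0]:
        raise ValueError("groups, times and events must be aligned")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"log-rank test requires exactly 2 groups, got {uniq.size}")
    in_a = labels == uniq[0]

    event_times = np.unique(times[events == 1])
    o_a = e_a = v = 0.0
    d_total_a = float(np.sum(events[in_a]))
    d_total_b = float(np.sum(events[~in_a]))
    for t in event_times:
        at_risk = times >= t
        n_j = float(np.sum(at_risk))
        n_aj = float(np.sum(at_risk & in_a))
        d_j = float(np.sum((times == t) & (events == 1)))
        d_aj = float(np.sum((times == t) & (events == 1) & in_a))
        o_a += d_aj
        e_a += d_j * n_aj / n_j
        if n_j > 1:
            v += d_j * (n_aj / n_j) * (1 - n_aj / n_j) * (n_j - d_j) / (n_j - 1)

    if v <= 0:
        warnings.warn("log-rank variance is zero; test carries no information",
                      stacklevel=2)
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o_a - e_a) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    total_events = d_total_a + d_total_b
    return LogRankResult(
        chi_square=float(chi2),
        p_value=max(p, np.finfo(float).tiny) if v > 0 else 1.0,
        observed={str(uniq[0]): d_total_a, str(uniq[1]): d_total_b},
        expected={str(uniq[0]): e_a, str(uniq[1]): total_events - e_a},
    )


def compare_expression_between_strata(
    values: pd.Series | dict, cohort: StratifiedCohort
) -> tuple[float, float]:
    """Welch two-sided t-test of a gene's expression between low and high.

    Returns ``(t, p)`` with t > 0 when the high stratum has the higher
    mean.  Each stratum needs >= 2 samples.
    """
    values = pd.Series(values, dtype=float)
    low = values[cohort.low].to_numpy()
    high = values[cohort.high].to_numpy()
    if low.size < 2 or high.size < 2:
        raise ValueError("each stratum needs >= 2 samples for a t-test")
    return welch_t_test(high, low)


def survival_analysis(
    clinical: ClinicalTable, tie_policy: str = "low"
) -> tuple[StratifiedCohort, dict[str, KMEstimate], LogRankResult]:
    """Median-split a clinical cohort and compare strata survival.

    Convenience wrapper: stratifies the ``expression`` covariate, fits a
    Kaplan-Meier curve per stratum and runs the log-rank test.
    """
    df = clinical.data
    cov = pd.Series(df["expression"].to_numpy(), index=df["sample"])
    cohort = stratify_by_median(cov, tie_policy=tie_policy)
    curves = {}
    for label in ("low", "high"):
        members = df["sample"].isin(getattr(cohort, label))
        curves[label] = km_estimate(
            df.loc[members, "os_time"], df.loc[members, "os_event"]
        )
    result = logrank_test(
        cohort.labels[df["sample"]].to_numpy(), df["os_time"], df["os_event"]
    )
    return cohort, curves, result
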