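"""Cell-line persistence curves, log-rank comparison, hazard ratios and nulls.

A persistence curve treats IC50 as "survival time": a cell line persists at
drug concentration t if its IC50 exceeds t, every observation is an event,
and the Kaplan-Meier estimate reduces to 1 minus the empirical CDF. Cohorts
of high- and low-scoring lines are compared by log-rank test and by the
hazard ratio of a proportional-hazards fit on the cohort indicator.

The null-distribution engine evaluates a metric on many random gene
signatures of the same length, drops degenerate evaluations, and locates
an observed signature's percentile within the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .core import DrugResponseTable

__all__ = [
    "PersistenceCurve",
    "LogRankResult",
    "NullDistribution",
    "persistence_curve",
    "logrank_test",
    "cohort_hazard_ratio",
    "sample_null_signatures",
    "build_null_distribution",
]

log = logging.getLogger(__name__)


@dataclass
class PersistenceCurve:
    """Step-function survival over IC50 with no censoring."""

    cohort_label: str
    event_times: np.ndarray        # sorted unique IC50 values
    survival_prob: np.ndarray      # S(t) just after each event time
    n_at_risk: np.ndarray          # number at risk just before each event time
    n: int

    @property
    def median(self) -> float:
        """Smallest event time t with S(t) <= 0.5."""
        idx = np.flatnonzero(self.survival_prob <= 0.5)
        return float(self.event_times[idx[0]]) if idx.size else float("nan")

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival_prob[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "survival": self.survival_prob,
            "at_risk": self.n_at_risk,
            "cohort": self.cohort_label,
        })


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p: float


@dataclass
class NullDistribution:
    metric_name: str
    values: np.ndarray
    n_requested: int
    n_degenerate: int
    observed: float
    percentile_of_observed: float
    null_signatures: list[set[str]] = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "n_requested": self.n_requested,
            "n_degenerate": self.n_degenerate,
            "observed": self.observed,
            "percentile_of_observed": self.percentile_of_observed,
            "null_median": float(np.median(self.values)),
            "null_p95": float(np.percentile(self.values, 95)),
        }


def persistence_curve(resp: DrugResponseTable, cohort: Iterable[str],
                      label: str = "") -> PersistenceCurve:
    """Kaplan-Meier estimate over IC50 with every observation an event.

    With no censoring the estimate equals 1 - ECDF exactly.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    missing = set(cohort) - set(resp.sample_ids)
    if missing:
        raise ValueError(f"cohort samples absent from response table: {sorted(missing)[:5]}")
    vals = np.sort(resp.ic50.loc[cohort].to_numpy())
    n = vals.size
    times, counts = np.unique(vals, return_counts=True)
    cum = np.cumsum(counts)
    surv = 1.0 - cum / n
    at_risk = n - np.concatenate([[0], cum[:-1]])
    return PersistenceCurve(label, times, surv, at_risk, n)


def logrank_test(resp: DrugResponseTable, cohort_a: set[str],
                 cohort_b: set[str]) -> LogRankResult:
    """Two-group log-rank test over IC50 event times (hypergeometric variance)."""
    if not cohort_a or not cohort_b:
        raise ValueError("both cohorts must be nonempty")
    if cohort_a & cohort_b:
        raise ValueError("cohorts overlap")
    ta = resp.ic50.loc[sorted(cohort_a)].to_numpy()
    tb = resp.ic50.loc[sorted(cohort_b)].to_numpy()
    res = _ll_logrank(ta, tb, event_observed_A=np.ones_like(ta),
                      event_observed_B=np.ones_like(tb))
    return LogRankResult(chi_square=float(res.test_statistic), df=1,
                         p=float(res.p_value))


def cohort_hazard_ratio(resp: DrugResponseTable, cohort_high: set[str],
                        cohort_low: set[str]) -> float:
    """Hazard ratio of the high-score cohort relative to the low-score cohort.

    Single-indicator proportional-hazards fit with IC50 as time, all events,
    Efron tie handling. HR > 1 means high-score lines reach their IC50 at
    lower concentrations (more drug-sensitive).
    """
    if cohort_high & cohort_low:
        raise ValueError("cohorts overlap")
    if len(cohort_high) < 5 or len(cohort_low) < 5:
        raise ValueError("each cohort needs >= 5 samples")
    high = sorted(cohort_high)
    low = sorted(cohort_low)
    df = pd.DataFrame({
        "time": np.concatenate([resp.ic50.loc[high], resp.ic50.loc[low]]),
        "event": 1,
        "high": [1] * len(high) + [0] * len(low),
    })
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise RuntimeError(f"proportional-hazards fit failed: {exc}") from exc
    return float(np.exp(cph.params_["high"]))


def sample_null_signatures(universe: Sequence[str], length: int, n: int,
                           seed: int) -> list[set[str]]:
    """``n`` random gene sets of the given length, sampled without replacement."""
    if length > len(universe):
        raise ValueError(f"signature length {length} exceeds universe size {len(universe)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    return [{universe[i] for i in rng.choice(len(universe), size=length, replace=False)}
            for _ in range(n)]


def build_null_distribution(
    metric_fn: Callable[[set[str]], float],
    nulls: list[set[str]],
    observed_signature: set[str],
    metric_name: str = "metric",
) -> NullDistribution:
    """Evaluate a metric on the null signatures and locate the observed one.

    ``metric_fn`` must return NaN for degenerate evaluations (e.g. constant
    predictions); those are dropped and counted. The percentile is the
    share of retained null values strictly below the observed value (ties
    count against the observed signature).
    """
    vals = np.array([metric_fn(sig) for sig in nulls], dtype=float)
    degenerate = ~np.isfinite(vals)
    kept = vals[~degenerate]
    if kept.size == 0:
        raise ValueError("all null evaluations were degenerate")
    observed = float(metric_fn(observed_signature))
    pct = 100.0 * float(np.sum(kept < observed)) / kept.size
    return NullDistribution(
        metric_name=metric_name,
        values=kept,
        n_requested=len(nulls),
        n_degenerate=int(degenerate.sum()),
        observed=observed,
        percentile_of_observed=pct,
        null_signatures=nulls,
    )
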