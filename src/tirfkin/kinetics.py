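"""Kinetic statistics: off-rates, Kaplan-Meier survival, log-rank, t-tests.

Off-rates use the occupancy-time estimator k = N_off / sum(T): the number of
observed detachments in a residence pool divided by the total observed
residence time of that pool, reported in events/hour.  For exponential
dwell times this is the maximum-likelihood rate, and right-censored
residences enter naturally — they add observation time but no event.  A
residence's single off-event is assigned to the ternary pool iff the
residence ever became ternary (T1/T2/T5 time > 0), else to the non-ternary
pool; the ternary pool's time is sum(T1+T2+T5) and the non-ternary pool's
sum(T3+T4), so a partner arrival that converts T3 into T5 is never itself
counted as a detachment.

Survival estimation is the product-limit (Kaplan-Meier) estimator with
exponential-Greenwood (log-log) 95% bands and the step-function median
(first observed time with S <= 0.5).  Group comparisons are the two-group
log-rank test for survival curves and the two-tailed unpaired equal-variance
t-test for replicate-level rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .pulses import Pulse
from .residence import ResidencePartition

__all__ = [
    "RateEstimate",
    "SurvivalCurve",
    "TestResult",
    "estimate_offrate",
    "estimate_offrate_replicates",
    "rate_from_durations",
    "km_estimate",
    "logrank_test",
    "compare_rates",
    "short_long_proportions",
    "photobleach_control_lifetimes",
]

SECONDS_PER_HOUR = 3600.0


@dataclass
class RateEstimate:
    """Off-rate k = N_off / total_time for one residence pool.

    ``per_replicate_k`` holds the replicate-level rates (h^-1) when the
    estimate aggregates several independent experiments; ``mean_k``/``sd_k``
    summarize them.  ``se`` is the per-pool asymptotic standard error
    k/sqrt(N) of the exponential-rate MLE.
    """

    pool: str
    n_off: int
    total_time: float  # s
    per_replicate_k: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_time <= 0:
            raise ValueError("total_time must be positive: rate undefined")
        if self.n_off < 0:
            raise ValueError("n_off must be non-negative")

    @property
    def k(self) -> float:
        """Pooled rate, events/h."""
        return self.n_off / (self.total_time / SECONDS_PER_HOUR)

    @property
    def se(self) -> float:
        """Asymptotic s.e. of the pooled rate (k/sqrt(N)), events/h."""
        return self.k / np.sqrt(self.n_off) if self.n_off > 0 else np.nan

    @property
    def mean_k(self) -> float:
        return float(np.mean(self.per_replicate_k)) if self.per_replicate_k else self.k

    @property
    def sd_k(self) -> float:
        if len(self.per_replicate_k) < 2:
            return np.nan
        return float(np.std(self.per_replicate_k, ddof=1))


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimate with 95% bands and the step-function median."""

    times: np.ndarray  # s, the estimator's step grid
    survival: np.ndarray  # S(t)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    at_risk: np.ndarray
    median: float  # s; nan when S never reaches 0.5
    n_total: int
    n_censored: int

    @property
    def median_defined(self) -> bool:
        return np.isfinite(self.median)

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        """Right-continuous step-function evaluation of S."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        s = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return s


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    kind: str  # "log_rank" | "unpaired_t_two_tailed"
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


# ---------------------------------------------------------------------------
# off-rates

def _pool_stats(
    partitions: list[ResidencePartition], pool: str
) -> tuple[int, float]:
    if pool not in ("ternary", "non_ternary"):
        raise ValueError("pool must be 'ternary' or 'non_ternary'")
    n_off = 0
    total = 0.0
    for p in partitions:
        if pool == "ternary":
            total += p.ternary_time
            if p.ever_ternary and p.off_event_observed:
                n_off += 1
        else:
            total += p.nonternary_time
            if not p.ever_ternary and p.off_event_observed:
                n_off += 1
    return n_off, total


def estimate_offrate(
    partitions: list[ResidencePartition], pool: str
) -> RateEstimate:
    """Off-rate of one residence pool from one dataset (events/h)."""
    n_off, total = _pool_stats(partitions, pool)
    if total <= 0.0:
        raise ValueError(f"empty {pool} pool: rate undefined")
    est = RateEstimate(pool, n_off, total)
    est.per_replicate_k.append(est.k)
    return est


def estimate_offrate_replicates(
    replicates: list[list[ResidencePartition]], pool: str
) -> RateEstimate:
    """Aggregate the pool off-rate over independent replicate experiments.

    The pooled rate uses summed events over summed time; replicate-level
    rates are kept for the mean +/- s.d. report and for t-tests.
    """
    per_k: list[float] = []
    n_off = 0
    total = 0.0
    for parts in replicates:
        n, t = _pool_stats(parts, pool)
        if t <= 0.0:
            raise ValueError(f"replicate with empty {pool} pool")
        per_k.append(n / (t / SECONDS_PER_HOUR))
        n_off += n
        total += t
    if not per_k:
        raise ValueError("no replicates")
    return RateEstimate(pool, n_off, total, per_replicate_k=per_k)


def rate_from_durations(
    durations: np.ndarray, censored: np.ndarray | None = None
) -> float:
    """Plain occupancy-time rate (events/h) from residence durations.

    ``censored[i]`` True marks a right-censored duration (time counted, no
    event).  This is the exponential-rate MLE and the building block of the
    pool estimators above.
    """
    durations = np.asarray(durations, dtype=float)
    if censored is None:
        censored = np.zeros(len(durations), dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    total = durations.sum()
    if total <= 0.0:
        raise ValueError("no observation time")
    return int((~censored).sum()) / (total / SECONDS_PER_HOUR)


# ---------------------------------------------------------------------------
# Kaplan-Meier

def km_estimate(
    durations: np.ndarray, censored: np.ndarray | None = None
) -> SurvivalCurve:
    """Product-limit survival estimate of residence durations.

    Right-censored observations are included unweighted (they remain in the
    risk set until their censoring time).  95% bands use the
    exponential-Greenwood log-log transform; the median is the first
    observed time with S(t) <= 0.5 and is nan when S never crosses 0.5
    (e.g. everything censored).
    """
    durations = np.asarray(durations, dtype=float)
    if len(durations) == 0:
        raise ValueError("no durations")
    if (durations <= 0).any():
        raise ValueError("durations must be positive")
    if censored is None:
        censored = np.zeros(len(durations), dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=~censored)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    times = sf.index.to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(sf.index).ffill().to_numpy(dtype=float)
    )
    median = float(kmf.median_survival_time_)
    if not np.isfinite(median):
        median = np.nan
    return SurvivalCurve(
        times=times,
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
        at_risk=at_risk,
        median=median,
        n_total=len(durations),
        n_censored=int(censored.sum()),
    )


def logrank_test(
    durations_a: np.ndarray,
    censored_a: np.ndarray,
    durations_b: np.ndarray,
    censored_b: np.ndarray,
) -> TestResult:
    """Two-group log-rank test (chi-square, 1 df).

    The chi-square upper-tail p is reported as-is and labeled two-tailed,
    the convention used when comparing two survival curves.
    """
    ca = np.asarray(censored_a, dtype=bool)
    cb = np.asarray(censored_b, dtype=bool)
    if len(durations_a) == 0 or len(durations_b) == 0:
        raise ValueError("both groups must be non-empty")
    if (~ca).sum() + (~cb).sum() == 0:
        raise ValueError("no events in either group: log-rank undefined")
    res = _ll_logrank(
        np.asarray(durations_a, dtype=float),
        np.asarray(durations_b, dtype=float),
        event_observed_A=~ca,
        event_observed_B=~cb,
    )
    return TestResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        kind="log_rank",
        n_a=len(durations_a),
        n_b=len(durations_b),
    )


def compare_rates(rates_a: list[float], rates_b: list[float]) -> TestResult:
    """Two-tailed unpaired equal-variance t-test on replicate-level rates."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, "unpaired_t_two_tailed", len(a), len(b))
        warnings.warn(
            "zero within-group variance with unequal means: p reported as 0",
            stacklevel=2,
        )
        return TestResult(np.inf, 0.0, "unpaired_t_two_tailed", len(a), len(b))
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(float(t), float(p), "unpaired_t_two_tailed", len(a), len(b))


# ---------------------------------------------------------------------------
# distribution summaries

def short_long_proportions(
    durations: np.ndarray, short_cut: float = 120.0, long_cut: float = 300.0
) -> tuple[float, float]:
    """(fraction strictly below short_cut, fraction strictly above long_cut)."""
    if not 0 < short_cut < long_cut:
        raise ValueError("require 0 < short_cut < long_cut")
    d = np.asarray(durations, dtype=float)
    if len(d) == 0:
        raise ValueError("no durations")
    return float((d < short_cut).mean()), float((d > long_cut).mean())


def photobleach_control_lifetimes(pulses: list[Pulse]) -> SurvivalCurve:
    """KM survival of ON durations from an immobilized-fluorophore control.

    In such a control every spot starts ON and loses signal only by
    photobleaching, so this curve is the bleaching survival used to judge
    whether measured residence lifetimes are photobleaching-limited.
    """
    if not pulses:
        raise ValueError("no pulses")
    durations = np.array([p.duration for p in pulses])
    censored = np.array([p.right_censored for p in pulses])
    return km_estimate(durations, censored)
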