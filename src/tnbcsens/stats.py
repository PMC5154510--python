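"""Statistical kernels shared across the pipeline.

Thin, contract-pinned wrappers: Fisher's exact test (two-sided, sum of
hypergeometric point probabilities <= observed), the Kaplan-Meier
product-limit estimator (events before censoring at tied times), the
two-group log-rank test, the Wilcoxon rank-sum test (normal approximation
with tie correction), and Spearman rank correlation (average ranks for
ties). The backends are scipy and lifelines; the tie conventions and
degenerate-input behavior declared here are what the test suite pins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps


@dataclass(frozen=True)
class SurvivalCurve:
    event_times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    events: tuple[int, ...]

    def __post_init__(self) -> None:
        surv = np.asarray(self.survival)
        if (np.diff(surv) > 1e-12).any():
            raise ValueError("survival curve must be non-increasing")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    A table with a zero margin carries no information: p = 1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("survival estimate requires at least one subject")
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    mask = tbl["observed"] > 0
    event_times = tbl.index[mask].to_numpy(dtype=float)
    survival = kmf.survival_function_.loc[event_times, "KM_estimate"].to_numpy()
    at_risk = tbl.loc[mask, "at_risk"].to_numpy(dtype=int)
    n_events = tbl.loc[mask, "observed"].to_numpy(dtype=int)
    return SurvivalCurve(
        event_times=tuple(event_times),
        survival=tuple(float(s) for s in survival),
        at_risk=tuple(int(a) for a in at_risk),
        events=tuple(int(e) for e in n_events),
    )


def logrank_test(group_labels, times, events) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p)."""
    labels = np.asarray(group_labels)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError(f"log-rank requires exactly 2 groups, got {groups.size}")
    a = labels == groups[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p, normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(
        sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")[1]
    )


def spearman_corr(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("samples must be non-empty and of equal length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(sps.spearmanr(x, y)[0])
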