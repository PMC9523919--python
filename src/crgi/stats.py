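"""Statistical primitives shared by every pipeline stage.

All hypothesis tests return a :class:`TestResult`; p-values always lie in
(0, 1] and degenerate inputs (constant data, no events) are flagged rather
than raising, so downstream stages can skip them explicitly.

Conventions
-----------
* Rank-sum tests are one-sided primitives: ``LESS`` means the *x* group
  tends to lower values than *y*.
* The rank-sum test switches to the exact (enumeration-equivalent)
  distribution when ``n_x + n_y <= 12`` and there are no ties; otherwise it
  uses the normal approximation with tie and continuity correction.  This
  makes small-sample behaviour deterministic and auditable.
* p-values are floored at 1e-300 before any log transform.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Alternative",
    "TestResult",
    "KMCurve",
    "rank_sum_test",
    "fisher_combine",
    "bh_adjust",
    "hypergeom_tail",
    "pearson",
    "two_sample_t",
    "chi_square_2x2",
    "km_curve",
    "logrank_test",
]

P_FLOOR = 1e-300
EXACT_MAX_N = 12


class Alternative(enum.Enum):
    LESS = "less"
    GREATER = "greater"
    TWO_SIDED = "two-sided"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-or-more-group hypothesis test."""

    statistic: float
    p_value: float
    alternative: Alternative
    n_x: int
    n_y: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _clip_p(p: float) -> float:
    return float(min(1.0, max(P_FLOOR, p)))


def _as_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def rank_sum_test(x, y, alternative: Alternative = Alternative.LESS) -> TestResult:
    """Wilcoxon–Mann–Whitney rank-sum test.

    ``LESS`` asks whether *x* tends to lower values than *y*.  Exact p by
    enumeration of rank assignments when the pooled sample is small and
    tie-free; normal approximation with tie and continuity correction
    otherwise.  Identical pooled values give p = 1 with the degenerate flag.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    pooled = np.concatenate([xa, ya])
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=float(xa.size * ya.size / 2.0),
            p_value=1.0,
            alternative=alternative,
            n_x=xa.size,
            n_y=ya.size,
            degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        xa, ya, alternative=alternative.value, method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=_clip_p(float(res.pvalue)),
        alternative=alternative,
        n_x=xa.size,
        n_y=ya.size,
    )


def fisher_combine(pvalues) -> float:
    """Fisher's combined probability: -2·Σ ln pᵢ ~ χ²(2k) upper tail.

    A single p-value is returned unchanged.
    """
    ps = np.asarray(pvalues, dtype=float).ravel()
    if ps.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(ps <= 0.0) or np.any(ps > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if ps.size == 1:
        return float(ps[0])
    stat = -2.0 * np.sum(np.log(np.clip(ps, P_FLOOR, 1.0)))
    return _clip_p(float(sps.chi2.sf(stat, df=2 * ps.size)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order kept."""
    ps = np.asarray(pvalues, dtype=float).ravel()
    if ps.size == 0:
        return np.empty(0)
    if np.any(ps <= 0.0) or np.any(ps > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    _, adj, _, _ = multipletests(ps, method="fdr_bh")
    return np.minimum(adj, 1.0)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) drawing n from N with K successes (log-space)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    return _clip_p(float(sps.hypergeom.sf(k - 1, N, K, n)))


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform.

    Raises ``ValueError`` when either input has zero variance; callers treat
    the pair as undefined and exclude it.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError("length mismatch")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(xa, ya)
    return float(r), _clip_p(float(p))


def two_sample_t(x, y) -> TestResult:
    """Welch two-sample t test, two-sided.

    Zero within-group variance in both groups is flagged degenerate: p = 1
    for equal means, a floored tiny p for distinct means.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size < 2 or ya.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(xa) == 0.0 and np.ptp(ya) == 0.0:
        if xa[0] == ya[0]:
            stat, p = 0.0, 1.0
        else:
            stat = math.inf if xa[0] > ya[0] else -math.inf
            p = P_FLOOR
        return TestResult(stat, p, Alternative.TWO_SIDED, xa.size, ya.size, degenerate=True)
    res = sps.ttest_ind(xa, ya, equal_var=False)
    return TestResult(
        statistic=float(res.statistic),
        p_value=_clip_p(float(res.pvalue)),
        alternative=Alternative.TWO_SIDED,
        n_x=xa.size,
        n_y=ya.size,
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1.

    Table layout: rows are groups, columns are outcomes → [[a, b], [c, d]].
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = sps.chi2_contingency(counts, correction=False)
    return TestResult(
        statistic=float(stat),
        p_value=_clip_p(float(p)),
        alternative=Alternative.TWO_SIDED,
        n_x=int(a + b),
        n_y=int(c + d),
    )


@dataclass
class KMCurve:
    """Right-continuous Kaplan–Meier product-limit estimate.

    ``times``/``survival`` hold the step positions; evaluation at an
    arbitrary time uses the last step at or before it (S(t<first) = 1).
    """

    times: np.ndarray
    survival: np.ndarray
    n: int
    n_events: int

    def __call__(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def as_table(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "survival": self.survival})


def km_curve(times, events) -> KMCurve:
    """Kaplan–Meier estimator; censored subjects leave the risk set silently."""
    t = _as_1d(times, "times")
    e = np.asarray(events, dtype=float).ravel()
    if t.size != e.size:
        raise ValueError("times and events length mismatch")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        n=t.size,
        n_events=int(e.sum()),
    )


def logrank_test(groups) -> TestResult:
    """Log-rank test across ≥2 groups; df = #groups − 1.

    ``groups`` is a sequence of ``(times, events)``.  With no events anywhere
    the test is undefined; p = 1 with the degenerate flag.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        ta = _as_1d(t, f"group {gi} times")
        ea = np.asarray(e, dtype=float).ravel()
        if ta.size != ea.size:
            raise ValueError(f"group {gi}: times/events length mismatch")
        if np.any(ta < 0):
            raise ValueError("negative survival time")
        times.append(ta)
        events.append(ea)
        labels.append(np.full(ta.size, gi))
    t_all = np.concatenate(times)
    e_all = np.concatenate(events)
    g_all = np.concatenate(labels)
    n_x, n_y = times[0].size, times[1].size
    if e_all.sum() == 0:
        return TestResult(0.0, 1.0, Alternative.TWO_SIDED, n_x, n_y, degenerate=True)
    res = multivariate_logrank_test(t_all, g_all, e_all)
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):  # all groups identical in events/risk structure
        return TestResult(0.0, 1.0, Alternative.TWO_SIDED, n_x, n_y, degenerate=True)
    return TestResult(stat, _clip_p(p), Alternative.TWO_SIDED, n_x, n_y)
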