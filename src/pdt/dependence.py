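"""Serial-dependence diagnostics: lag-1 autocorrelation and Ljung-Box tests.

The distancing test thins a series into ``k`` interleaved subsets and needs to
know at which distance ``k`` serial autocorrelation is no longer significantly
present.  Each subset is screened with a lag-1 Ljung-Box portmanteau test; the
``k`` per-subset results are summarised by the mean lag-1 autocorrelation, the
mean Q statistic, and a Fisher-combined p-value which drives the gate.

Missing values inside a subset are dropped and the retained values treated as a
regular series: within a subset retained observations are equally spaced by
construction, so dropping an isolated gap preserves the spacing interpretation.
"""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LjungBoxResult",
    "LjungBoxSummary",
    "lag1_autocorrelation",
    "ljung_box",
    "combine_dependence",
]

#: floor applied to p-values before taking logs in Fisher's combination
P_FLOOR = 1e-16


class LjungBoxResult(NamedTuple):
    n: int
    r1: float
    Q: float
    df: int
    p: float


class LjungBoxSummary(NamedTuple):
    """Per-distance summary over the k subsets."""

    k: int
    mean_r1: float
    mean_Q: float
    combined_p: float


def _clean(values: Sequence[float]) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("need >=3 non-missing values")
    return x


def _autocorrelations(x: np.ndarray, lags: int) -> np.ndarray:
    xc = x - x.mean()
    denom = float(np.sum(xc * xc))
    if denom == 0.0:
        raise ValueError("degenerate series: zero variance")
    return np.array([float(np.sum(xc[:-j] * xc[j:])) / denom for j in range(1, lags + 1)])


def lag1_autocorrelation(values: Sequence[float]) -> float:
    """Sample lag-1 autocorrelation, missing entries dropped.

    r1 = sum (x_t - xbar)(x_{t+1} - xbar) / sum (x_t - xbar)^2, the standard
    biased estimator whose denominator runs over all retained values.
    """
    return float(_autocorrelations(_clean(values), 1)[0])


def ljung_box(values: Sequence[float], lags: int = 1) -> LjungBoxResult:
    """Ljung-Box portmanteau test on the retained (non-missing) values.

    Q = n(n+2) * sum_{j=1..lags} r_j^2 / (n-j), referred to a chi-square with
    ``lags`` degrees of freedom (upper tail).  The default single lag targets
    the first-order dependence the distancing procedure is designed to remove.
    """
    x = _clean(values)
    n = len(x)
    if lags < 1 or lags >= n:
        raise ValueError("lags must be in [1, n-1]")
    r = _autocorrelations(x, lags)
    q = float(n * (n + 2) * np.sum(r**2 / (n - np.arange(1, lags + 1))))
    return LjungBoxResult(n=n, r1=float(r[0]), Q=q, df=lags, p=float(stats.chi2.sf(q, lags)))


def combine_dependence(per_subset: Sequence[LjungBoxResult], k: int) -> LjungBoxSummary:
    """Summarise the k per-subset Ljung-Box results for one distance.

    Means of r1 and Q, plus Fisher's combination of the subset p-values
    (-2 sum log p against chi-square with 2k df).  For k=1 the combined p is
    the single subset's p.  p-values are floored at ``P_FLOOR`` before logs.
    """
    if len(per_subset) != k:
        raise ValueError(f"expected {k} subset results, got {len(per_subset)}")
    ps = np.maximum([r.p for r in per_subset], P_FLOOR)
    if k == 1:
        combined = float(per_subset[0].p)
    else:
        fisher = -2.0 * float(np.sum(np.log(ps)))
        combined = float(stats.chi2.sf(fisher, 2 * k))
    return LjungBoxSummary(
        k=k,
        mean_r1=float(np.mean([r.r1 for r in per_subset])),
        mean_Q=float(np.mean([r.Q for r in per_subset])),
        combined_p=combined,
    )
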