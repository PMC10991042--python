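"""Benchmark tests: traditional permutation test and the randomization (SCRT) test.

The traditional permutation test freely reassigns all observations to the two
phases, ignoring serial dependence -- it is exact for exchangeable data but
anti-conservative for autocorrelated series.  The single-case randomization
test (SCRT) instead builds its null distribution from the admissible starting
points of the intervention phase: each admissible division of the observation
sequence into a leading A-stretch and trailing B-stretch contributes one
statistic, and the p-value is the proportion of divisions (the observed one
included) at least as extreme as the observed division.  The SCRT is the
design-based test when the start point was randomized; on observational data
it serves as a conservative benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .distancing import Sided, Statistic, _count_extreme, _permutation_p, _phase_diff
from .series import ABSeries

__all__ = ["RandomizationResult", "traditional_permutation_test", "scrt"]


@dataclass(frozen=True)
class RandomizationResult:
    observed_statistic: float
    p: float
    n_randomizations: int
    method: Literal["traditional", "scrt"]


def traditional_permutation_test(
    series: ABSeries,
    statistic: Statistic = "mean",
    n_permutations: int = 10_000,
    sided: Sided = "two",
    rng: np.random.Generator | None = None,
) -> RandomizationResult:
    """Permutation test that freely reassigns all non-missing values to the phases.

    Identical to the distance-1 subset test of the distancing procedure.
    Exhaustive enumeration is used when the number of distinct assignments does
    not exceed ``n_permutations``.
    """
    values, phases = series.observed()
    is_a = phases == "A"
    if rng is None:
        rng = np.random.default_rng()
    obs = _phase_diff(values, is_a, statistic)
    p = _permutation_p(values, is_a, statistic, n_permutations, sided, rng)
    from math import comb

    n_rand = min(comb(len(values), int(is_a.sum())), n_permutations)
    return RandomizationResult(
        observed_statistic=float(obs), p=float(p), n_randomizations=n_rand, method="traditional"
    )


def scrt(
    series: ABSeries,
    n1_min: int = 1,
    statistic: Statistic = "mean",
    sided: Sided = "greater",
    lag: int = 0,
) -> RandomizationResult:
    """Randomization test over admissible intervention start points.

    Divisions are taken on the sequence of non-missing observations: every
    admissible start point leaves at least ``n1_min`` observations in each
    stretch.  ``lag`` shifts the observed phase boundary forward by that many
    observations, for designs where the treatment response is hypothesised to
    set in with a delay after the intervention started.  The default one-sided
    direction (``"greater"``) treats a large A-minus-B difference -- a drop in
    the outcome after the start point -- as the hypothesised improvement.
    """
    if n1_min < 1:
        raise ValueError("n1_min must be >= 1")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    values, phases = series.observed()
    n = len(values)
    n_a_obs = int(np.sum(phases == "A")) + lag
    if not 1 <= n_a_obs <= n - 1:
        raise ValueError("lagged phase boundary leaves an empty phase")
    starts = [s for s in range(n1_min, n - n1_min + 1)]
    if len(starts) < 2:
        raise ValueError("fewer than two admissible start points")
    if n_a_obs not in starts:
        raise ValueError(
            f"observed division (nA={n_a_obs}) is not admissible under n1_min={n1_min}"
        )
    stats = np.empty(len(starts))
    for i, s in enumerate(starts):
        is_a = np.zeros(n, dtype=bool)
        is_a[:s] = True
        stats[i] = _phase_diff(values, is_a, statistic)
    obs = stats[starts.index(n_a_obs)]
    p = _count_extreme(stats, obs, sided) / len(starts)
    return RandomizationResult(
        observed_statistic=float(obs), p=float(p), n_randomizations=len(starts), method="scrt"
    )
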