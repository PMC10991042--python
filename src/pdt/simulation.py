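"""Monte Carlo validation framework: AR(1) two-phase generator and power study.

Series are generated from a simplified two-phase level-change regression

    Y_t = b0 + b2 * D_t + e_t,      t = 1..Ns,

where ``D_t`` is the intervention dummy (0 in phase A, 1 in phase B) and the
errors are first-order autoregressive, ``e_t = ar1 * e_{t-1} + z_t`` with
standard-normal innovations (``ar1 = 0`` reduces to iid standard normal).
The phase-A length ``nA`` is drawn uniformly from ``[n1_limit, Ns-n1_limit]``,
emulating a randomized intervention start so the same replications can also be
analysed with the randomization (SCRT) test.  Optional linear-trend
coefficients ``b1`` (phase-A slope) and ``b3`` (extra phase-B slope) are
exposed as hooks and default to zero.

``run_cell`` estimates a rejection proportion for one factor-level combination
and one test; ``run_power_study`` crosses full factor grids in independent
batches so that across-batch confidence intervals can be reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps
from scipy.signal import lfilter

from .comparison import scrt, traditional_permutation_test
from .distancing import PDTConfig, run_pdt
from .series import ABSeries

__all__ = [
    "SimulationConfig",
    "MonteCarloDesign",
    "PowerEstimate",
    "generate_series",
    "run_cell",
    "run_power_study",
    "tidy_frame",
]

logger = logging.getLogger(__name__)

TestName = Literal["pdt", "traditional", "scrt"]

#: pre-sample steps discarded so the AR(1) error process forgets its start
BURN_IN = 100


@dataclass(frozen=True)
class SimulationConfig:
    """Generating-model parameters for one simulated series."""

    Ns: int
    b2: float
    ar1: float = 0.0
    b0: float = 0.0
    n1_limit: int = 5
    b1: float = 0.0  # phase-A linear trend (hook, unused in the validation grid)
    b3: float = 0.0  # additional phase-B trend (hook)

    def __post_init__(self) -> None:
        if self.Ns < 2 * self.n1_limit:
            raise ValueError("Ns must be >= 2 * n1_limit")
        if not abs(self.ar1) < 1:
            raise ValueError("|ar1| must be < 1 (stationary errors)")
        if self.n1_limit < 1:
            raise ValueError("n1_limit must be >= 1")


def generate_series(config: SimulationConfig, rng: np.random.Generator) -> ABSeries:
    """Draw one AB-phase series from the generating model.

    AR(1) innovations have unit variance and are not re-normalised, so the
    marginal error variance is ``1 / (1 - ar1**2)``; a 100-step burn-in removes
    the initialisation transient.
    """
    n_a = int(rng.integers(config.n1_limit, config.Ns - config.n1_limit, endpoint=True))
    z = rng.standard_normal(config.Ns + BURN_IN)
    if config.ar1 != 0.0:
        eps = lfilter([1.0], [1.0, -config.ar1], z)[BURN_IN:]
    else:
        eps = z[BURN_IN:]
    t = np.arange(1, config.Ns + 1, dtype=float)
    d = (t > n_a).astype(float)
    y = config.b0 + config.b1 * t + config.b2 * d + config.b3 * d * (t - n_a) + eps
    return ABSeries(
        time=np.arange(1, config.Ns + 1),
        phase=np.where(d > 0, "B", "A"),
        y=y,
    )


def _resolve_sided(sided: str, b2: float) -> str:
    """``"auto"`` = one-sided toward the generated effect.

    The study-design reading: each cell tests the hypothesised improvement
    direction, here the sign of the level change (statistic is A minus B, so a
    positive ``b2`` makes phase B larger and the extreme direction "less").
    Under the null (``b2 = 0``) the direction is immaterial by symmetry.
    """
    if sided != "auto":
        return sided
    return "less" if b2 > 0 else "greater"


def _apply_test(
    series: ABSeries,
    test: TestName,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_permutations: int,
    sided: str,
    p_source: str,
) -> float:
    sided = _resolve_sided(sided, config.b2)
    if test == "pdt":
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # residual-autocorrelation warnings
            result = run_pdt(
                series,
                PDTConfig(
                    n_permutations=n_permutations,
                    sided=sided,
                    seed=int(rng.integers(2**31)),
                ),
            )
        return result.favored_row.raw_p if p_source == "raw" else result.p_value
    if test == "traditional":
        return traditional_permutation_test(
            series, n_permutations=n_permutations, sided=sided, rng=rng
        ).p
    if test == "scrt":
        return scrt(series, n1_min=config.n1_limit, sided=sided).p
    raise ValueError(f"unknown test {test!r}")


def run_cell(
    cell: SimulationConfig,
    test: TestName,
    replications: int,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    n_permutations: int = 1000,
    sided: str = "auto",
    p_source: str = "raw",
) -> float:
    """Rejection proportion of one test over replications of one design cell.

    For the distancing test a replication rejects on the favored distance's
    raw (mean per-subset) permutation p; ``p_source="fitted"`` switches to the
    smoothed p-curve value instead.  Rejection is ``p <= alpha`` -- the
    equality matters because randomization-test p-values are granular (e.g.
    the smallest SCRT p with 21 admissible start points is 1/21 = 0.048, which
    must count for the SCRT to have any power).  Failed replications are
    logged and redrawn, never silently dropped.
    """
    if rng is None:
        rng = np.random.default_rng()
    rejections = 0
    done = 0
    attempts = 0
    while done < replications:
        attempts += 1
        if attempts > 2 * replications + 100:
            raise RuntimeError("too many failed replications")
        series = generate_series(cell, rng)
        try:
            p = _apply_test(series, test, cell, rng, n_permutations, sided, p_source)
        except ValueError as exc:  # degenerate draw: redraw and log
            logger.warning("replication failed (%s); redrawing", exc)
            continue
        rejections += p <= alpha
        done += 1
    return rejections / replications


@dataclass(frozen=True)
class MonteCarloDesign:
    """Factor grids and execution profile of a power study.

    The full validation grid is ``ar1 x Ns x b2 x n1_limit`` =
    {0,.15,.30,.45,.60} x {30,60,90,120} x {-2,-1,0,1,2} x {5,10} = 200 cells,
    each test estimated in ``batches`` independent batches of ``replications``
    series.  The defaults here are a desk-scale profile (200 replications per
    batch, 1000 permutations); the cluster-scale study uses 1000 replications.
    """

    ar1_levels: Sequence[float] = (0.0, 0.15, 0.30, 0.45, 0.60)
    ns_levels: Sequence[int] = (30, 60, 90, 120)
    b2_levels: Sequence[float] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    n1_levels: Sequence[int] = (5, 10)
    tests: Sequence[TestName] = ("pdt", "scrt", "traditional")
    replications: int = 200
    batches: int = 5
    alpha: float = 0.05
    n_permutations: int = 1000
    sided: str = "auto"
    p_source: str = "raw"
    seed: int = 0

    def cells(self) -> list[SimulationConfig]:
        return [
            SimulationConfig(Ns=ns, b2=b2, ar1=ar1, n1_limit=n1)
            for ar1, ns, b2, n1 in product(
                self.ar1_levels, self.ns_levels, self.b2_levels, self.n1_levels
            )
        ]


@dataclass(frozen=True)
class PowerEstimate:
    """Per-batch rejection proportions of one test in one design cell."""

    cell: SimulationConfig
    test: TestName
    proportions: tuple[float, ...]
    mean: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions)
        m = float(p.mean())
        if len(p) > 1 and p.std(ddof=1) > 0:
            half = float(sps.t.ppf(0.975, len(p) - 1) * p.std(ddof=1) / np.sqrt(len(p)))
        else:
            half = 0.0
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "ci_low", max(0.0, m - half))
        object.__setattr__(self, "ci_high", min(1.0, m + half))


def run_power_study(design: MonteCarloDesign) -> list[PowerEstimate]:
    """Estimate rejection proportions for every cell x test of the design.

    Every (cell, test, batch) gets its own child seed spawned from
    ``design.seed`` in a fixed order, so the full study table is reproducible
    and any subset of it can be recomputed independently.
    """
    cells = design.cells()
    ss = np.random.SeedSequence(design.seed)
    children = iter(ss.spawn(len(cells) * len(design.tests) * design.batches))
    out: list[PowerEstimate] = []
    for cell in cells:
        for test in design.tests:
            props = []
            for _ in range(design.batches):
                rng = np.random.default_rng(next(children))
                props.append(
                    run_cell(
                        cell,
                        test,
                        design.replications,
                        design.alpha,
                        rng,
                        design.n_permutations,
                        design.sided,
                        design.p_source,
                    )
                )
            out.append(PowerEstimate(cell=cell, test=test, proportions=tuple(props)))
    return out


def tidy_frame(estimates: Sequence[PowerEstimate]):
    """One row per cell x test x batch, ready for CSV export or plotting."""
    import pandas as pd

    rows = []
    for e in estimates:
        for b, p in enumerate(e.proportions, start=1):
            rows.append(
                {
                    "ar1": e.cell.ar1,
                    "Ns": e.cell.Ns,
                    "b2": e.cell.b2,
                    "n1_limit": e.cell.n1_limit,
                    "test": e.test,
                    "batch": b,
                    "rejection_proportion": p,
                    "mean": e.mean,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                }
            )
    return pd.DataFrame(rows)
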