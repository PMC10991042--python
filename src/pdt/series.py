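"""Single-case AB-phase series: data model, equidistance preprocessing, trends.

An AB-phase single-case series is a sequence of repeated measurements on one
subject, split into a baseline phase (``A``) and an intervention phase (``B``).
The distancing machinery in :mod:`pdt.distancing` requires the series to be
*equidistant*: every integer time marker between the first and the last must be
present exactly once, with a missing outcome (NaN) wherever no observation was
made.  :func:`make_equidistant` establishes that form from raw records by
inserting absent markers and resolving duplicated markers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RawRecord",
    "ABSeries",
    "PhaseSummary",
    "TrendEstimate",
    "make_equidistant",
    "phase_summary",
    "inspect_trend",
    "detrend",
]

logger = logging.getLogger(__name__)

PHASES = ("A", "B")


class RawRecord(NamedTuple):
    """One observation: integer time marker, phase label, outcome (NaN = missing)."""

    time: int
    phase: str
    y: float


@dataclass(frozen=True)
class ABSeries:
    """Equidistant single-case AB-phase series.

    Attributes
    ----------
    time
        Strictly increasing consecutive integers (step 1).
    phase
        Array of ``"A"``/``"B"`` labels; all A's precede all B's.
    y
        Outcomes; ``NaN`` marks a missing observation.
    log
        Preprocessing mutations applied by :func:`make_equidistant`.
    """

    time: np.ndarray
    phase: np.ndarray
    y: np.ndarray
    log: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=int)
        phase = np.asarray(self.phase, dtype="U1")
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "phase", phase)
        object.__setattr__(self, "y", y)
        if not (len(time) == len(phase) == len(y)):
            raise ValueError("time, phase and y must have equal length")
        if len(time) == 0:
            raise ValueError("empty series")
        if np.any(np.diff(time) != 1):
            raise ValueError("time markers must be consecutive integers (equidistant, step 1)")
        bad = set(np.unique(phase)) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        is_b = phase == "B"
        if np.any(np.diff(is_b.astype(int)) < 0):
            raise ValueError("phase labels must be non-decreasing (all A before all B)")
        for ph in PHASES:
            sel = phase == ph
            if not sel.any() or not np.isfinite(y[sel]).any():
                raise ValueError(f"phase without observations: {ph}")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_phase_a(self) -> int:
        return int(np.sum(self.phase == "A"))

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Non-missing outcomes and their phase labels, in time order."""
        m = np.isfinite(self.y)
        return self.y[m], self.phase[m]

    @classmethod
    def from_records(cls, records: Iterable[RawRecord]) -> "ABSeries":
        recs = list(records)
        return cls(
            time=np.array([r.time for r in recs]),
            phase=np.array([r.phase for r in recs]),
            y=np.array([math.nan if r.y is None else float(r.y) for r in recs]),
        )

    def to_records(self) -> list[RawRecord]:
        return [RawRecord(int(t), str(p), float(v)) for t, p, v in zip(self.time, self.phase, self.y)]


class PhaseSummary(NamedTuple):
    """Per-phase counts, means, medians and sample SDs (denominator n-1)."""

    nA: int
    nB: int
    meanA: float
    meanB: float
    medianA: float
    medianB: float
    sdA: float
    sdB: float


class TrendEstimate(NamedTuple):
    """OLS slope of y on time within one phase, with its two-sided p-value."""

    phase: str
    slope: float
    intercept: float
    p_value: float
    n: int


def _coerce_records(records: Sequence[RawRecord]) -> list[RawRecord]:
    out = []
    for r in records:
        t, ph, y = r
        if ph not in PHASES:
            raise ValueError(f"unknown phase label {ph!r} at time {t}")
        t = int(t)
        y = math.nan if y is None else float(y)
        out.append(RawRecord(t, ph, y))
    return out


def make_equidistant(records: Sequence[RawRecord]) -> ABSeries:
    """Return an equidistant :class:`ABSeries` from possibly gappy/duplicated records.

    Absent time markers are inserted with a missing outcome; their phase is the
    phase of the block they fall in (before the first B-labelled marker -> A).
    Duplicated markers are resolved in the order: shift the first duplicate's
    outcome to the preceding marker if that one is missing, else shift the last
    duplicate's outcome to the following marker if missing, else replace the
    duplicates by their mean.  Every mutation is recorded in ``ABSeries.log``.
    """
    recs = sorted(_coerce_records(records), key=lambda r: r.time)
    if not recs:
        raise ValueError("no records")
    for ph in PHASES:
        if not any(r.phase == ph and math.isfinite(r.y) for r in recs):
            raise ValueError(f"phase without observations: {ph}")

    by_time: dict[int, list[RawRecord]] = {}
    for r in recs:
        by_time.setdefault(r.time, []).append(r)
    for t, rs in by_time.items():
        if len({r.phase for r in rs}) > 1:
            raise ValueError(f"conflicting phase labels at time marker {t}")

    b_times = [r.time for r in recs if r.phase == "B"]
    first_b = min(b_times) if b_times else None

    def block_phase(t: int) -> str:
        return "A" if first_b is None or t < first_b else "B"

    t_min, t_max = recs[0].time, recs[-1].time
    log: list[str] = []
    # observed value per marker; duplicates kept aside for resolution
    values: dict[int, float] = {}
    phases: dict[int, str] = {}
    for t in range(t_min, t_max + 1):
        rs = by_time.get(t, [])
        phases[t] = rs[0].phase if rs else block_phase(t)
        if not rs:
            values[t] = math.nan
            log.append(f"inserted missing time marker {t} (phase {phases[t]})")
        elif len(rs) == 1:
            values[t] = rs[0].y
        else:
            values[t] = math.nan  # placeholder, resolved below

    for t in range(t_min, t_max + 1):
        rs = by_time.get(t, [])
        if len(rs) <= 1:
            continue
        ys = [r.y for r in rs]
        prev_free = t - 1 >= t_min and not math.isfinite(values.get(t - 1, math.nan))
        next_rs = by_time.get(t + 1, [])
        next_free = (
            t + 1 <= t_max and len(next_rs) <= 1 and not math.isfinite(values.get(t + 1, math.nan))
        )
        if prev_free:
            values[t - 1] = ys[0]
            values[t] = ys[1] if len(ys) == 2 else float(np.nanmean(ys[1:]))
            log.append(f"shifted first duplicate of marker {t} back to marker {t - 1}")
        elif next_free:
            values[t + 1] = ys[-1]
            values[t] = ys[0] if len(ys) == 2 else float(np.nanmean(ys[:-1]))
            log.append(f"shifted last duplicate of marker {t} forward to marker {t + 1}")
        else:
            values[t] = float(np.nanmean(ys))
            log.append(f"mean-aggregated {len(ys)} duplicates at marker {t}")

    times = np.arange(t_min, t_max + 1)
    for msg in log:
        logger.info("%s", msg)
    return ABSeries(
        time=times,
        phase=np.array([phases[t] for t in times]),
        y=np.array([values[t] for t in times]),
        log=tuple(log),
    )


def _phase_values(series: ABSeries, ph: str) -> np.ndarray:
    v = series.y[series.phase == ph]
    return v[np.isfinite(v)]


def phase_summary(series: ABSeries) -> PhaseSummary:
    """Counts, means, medians and sample SDs of the non-missing values per phase.

    A phase with fewer than two non-missing values gets ``NaN`` (not zero) as SD.
    """
    a = _phase_values(series, "A")
    b = _phase_values(series, "B")
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) >= 2 else math.nan
    return PhaseSummary(
        nA=len(a),
        nB=len(b),
        meanA=float(np.mean(a)),
        meanB=float(np.mean(b)),
        medianA=float(np.median(a)),
        medianB=float(np.median(b)),
        sdA=sd(a),
        sdB=sd(b),
    )


def inspect_trend(series: ABSeries, which_phases: Iterable[str] = PHASES) -> list[TrendEstimate]:
    """Per-phase OLS slope of y on time, with the two-sided slope-test p-value.

    Requires at least three non-missing points in each inspected phase.  A clear
    nonzero slope means the series violates the no-linear-trend assumption of
    the distancing test; consider :func:`detrend` (and interpret with care).
    """
    out = []
    for ph in which_phases:
        if ph not in PHASES:
            raise ValueError(f"unknown phase {ph!r}")
        sel = series.phase == ph
        t = series.time[sel].astype(float)
        v = series.y[sel]
        m = np.isfinite(v)
        if m.sum() < 3:
            raise ValueError(f"phase {ph}: need >=3 non-missing points to estimate a trend")
        res = stats.linregress(t[m], v[m])
        out.append(
            TrendEstimate(
                phase=ph,
                slope=float(res.slope),
                intercept=float(res.intercept),
                p_value=float(res.pvalue),
                n=int(m.sum()),
            )
        )
    return out


def detrend(series: ABSeries, which_phases: Iterable[str] = PHASES) -> ABSeries:
    """Subtract the within-phase OLS trend, preserving each phase mean exactly.

    Only the selected phases are modified.  The phase mean is added back after
    removing the fitted line, so the phase-mean difference -- the statistic the
    distancing test works on -- is untouched by construction.
    """
    y = series.y.copy()
    for est in inspect_trend(series, which_phases):
        sel = series.phase == est.phase
        t = series.time[sel].astype(float)
        v = y[sel]
        m = np.isfinite(v)
        fitted = est.intercept + est.slope * t[m]
        v[m] = v[m] - fitted + np.mean(v[m])
        y[sel] = v
    return ABSeries(time=series.time, phase=series.phase, y=y, log=series.log)
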