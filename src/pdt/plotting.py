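"""Plots: series inspection and power curves."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .series import ABSeries, phase_summary
from .simulation import PowerEstimate

__all__ = ["plot_series", "plot_power_curves"]


def plot_series(series: ABSeries, statistic: str = "mean", cutoff: float | None = None, ax=None):
    """Plot the two phases in distinct colours with per-phase centre lines.

    The horizontal lines show the per-phase mean (or median); an optional
    clinical cut-off can be drawn as a dashed reference line.  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    summ = phase_summary(series)
    centres = {
        "A": summ.medianA if statistic == "median" else summ.meanA,
        "B": summ.medianB if statistic == "median" else summ.meanB,
    }
    colors = {"A": "tab:blue", "B": "tab:red"}
    for ph in ("A", "B"):
        sel = series.phase == ph
        ax.plot(series.time[sel], series.y[sel], "o-", color=colors[ph], label=f"Phase {ph}")
        t = series.time[sel]
        ax.hlines(centres[ph], t.min(), t.max(), color=colors[ph], lw=2, alpha=0.6)
    if cutoff is not None:
        ax.axhline(cutoff, color="black", ls="--", lw=1, label="cut-off")
    ax.set_xlabel("time")
    ax.set_ylabel("y")
    ax.legend(loc="best", fontsize=8)
    return ax


def plot_power_curves(estimates: Sequence[PowerEstimate], ns: int, n1_limit: int, ax=None):
    """Power (rejection proportion) vs autocorrelation, one panel per effect size.

    Mirrors the validation-study figures: mean across batches with 95% CI,
    80% and 5% reference lines, one colour per test.
    """
    import matplotlib.pyplot as plt

    sel = [e for e in estimates if e.cell.Ns == ns and e.cell.n1_limit == n1_limit]
    b2s = sorted({e.cell.b2 for e in sel})
    if ax is None:
        _, axes = plt.subplots(1, len(b2s), figsize=(3 * len(b2s), 3), sharey=True)
        axes = np.atleast_1d(axes)
    else:
        axes = np.atleast_1d(ax)
    colors = {"pdt": "tab:blue", "scrt": "tab:red", "traditional": "tab:green"}
    for a, b2 in zip(axes, b2s):
        for test in sorted({e.test for e in sel}):
            pts = sorted(
                [e for e in sel if e.cell.b2 == b2 and e.test == test], key=lambda e: e.cell.ar1
            )
            x = [e.cell.ar1 for e in pts]
            y = [e.mean for e in pts]
            lo = [e.mean - e.ci_low for e in pts]
            hi = [e.ci_high - e.mean for e in pts]
            a.errorbar(x, y, yerr=[lo, hi], color=colors.get(test, "gray"), marker="o", label=test)
        a.axhline(0.80, color="black", lw=1)
        a.axhline(0.05, color="black", lw=1)
        a.set_title(f"b2 = {b2:g}")
        a.set_xlabel("ar1")
        a.set_ylim(-0.02, 1.02)
    axes[0].set_ylabel("rejection proportion")
    axes[-1].legend(fontsize=7)
    return axes
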