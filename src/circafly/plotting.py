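"""Visualisation utilities: double-plotted actograms and periodogram curves.

Rendering is provided for human inspection of rhythmicity calls (the
protocol this package models confirms periodogram calls by eye); nothing
downstream depends on these figures.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .dam_io import ActivitySeries
from .periodogram import PeriodogramResult


def actogram(series: ActivitySeries, ax=None, double_plot: bool = True):
    """Raster actogram: one row per day, counts as filled bars, modulo 24 h.

    With ``double_plot`` each row shows 48 h (day i followed by day i+1),
    the standard layout for judging free-running rhythms by eye.
    """
    import matplotlib.pyplot as plt

    bins_per_day = int(round(1440.0 / series.bin_minutes))
    n_days = series.n_bins // bins_per_day
    grid = series.counts[: n_days * bins_per_day].reshape(n_days, bins_per_day).astype(float)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.3 * n_days + 1))
    peak = grid.max() or 1.0
    width = 2 if double_plot else 1
    hours = np.arange(width * bins_per_day) * series.bin_minutes / 60.0
    for day in range(n_days):
        row = grid[day]
        if double_plot:
            nxt = grid[day + 1] if day + 1 < n_days else np.zeros_like(row)
            row = np.concatenate([row, nxt])
        ax.bar(
            hours,
            row / peak * 0.9,
            bottom=n_days - 1 - day,
            width=series.bin_minutes / 60.0,
            align="edge",
            color="black",
            linewidth=0,
        )
    ax.set_xlim(0, width * 24)
    ax.set_ylim(0, n_days)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("day")
    ax.set_yticks(np.arange(n_days) + 0.5, [str(n_days - d) for d in range(n_days)])
    ax.set_title(f"{series.fly_id} ({series.genotype})")
    return ax


def periodogram_plot(result: PeriodogramResult, ax=None, label: Optional[str] = None):
    """Qp versus trial period with the chi-square significance line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.trial_periods_hours, result.qp, color="black", label=label or "Qp")
    ax.plot(
        result.trial_periods_hours,
        result.sig_line,
        color="red",
        linestyle="--",
        label=f"chi-square {1 - result.alpha:.0%} line",
    )
    if result.rhythmic:
        ax.axvline(result.peak_period_hours, color="grey", linewidth=0.8)
    ax.set_xlabel("trial period (h)")
    ax.set_ylabel("Qp")
    ax.legend(frameon=False)
    return ax
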