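"""Plots for screening and time-lapse readouts (matplotlib)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quantify import DoseResponseResult, IntensityComparison
from .timelapse import TimeSeries


def plot_dose_response(result: DoseResponseResult, ax=None):
    """Dose–response scatter with the fitted 4PL curve on a log-x axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.semilogx(result.concentrations, result.responses, "ko", label="observed")
    if result.converged:
        grid = np.geomspace(result.concentrations.min(), result.concentrations.max(), 200)
        ax.semilogx(grid, result.predict(grid), "r-", label="4PL fit")
        ax.axvline(result.ic50, color="r", ls="--", lw=0.8)
        ax.annotate(f"IC50 = {result.ic50:.3g}", (result.ic50, result.top), fontsize=8)
    ax.set_xlabel("concentration")
    ax.set_ylabel("normalized viability")
    ax.legend(frameon=False)
    return ax


def plot_timeseries(ts: TimeSeries, ax=None):
    """Non-PGCC (left axis, black) and PGCC (right axis, red) counts over time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hours = ts.times / 60.0
    ax.plot(hours, ts.n_non_pgcc, "k-o", ms=3)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("non-PGCCs", color="k")
    ax2 = ax.twinx()
    ax2.plot(hours, ts.n_pgcc, "r-o", ms=3)
    ax2.set_ylabel("PGCCs", color="r")
    return ax


def plot_gating(records: pd.DataFrame, gates=None, ax=None):
    """Live vs dead mean-intensity scatter (log axes) with quadrant gates."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"live": "tab:green", "dead": "tab:red", "unassigned": "gray"}
    for cls, grp in records.groupby("viability"):
        ax.loglog(
            grp["mean_live"] + 1, grp["mean_dead"] + 1, ".",
            color=colors.get(cls, "gray"), label=cls, ms=3,
        )
    if gates is not None:
        ax.axvline(gates.live_threshold + 1, color="k", lw=0.8, ls="--")
        ax.axhline(gates.dead_threshold + 1, color="k", lw=0.8, ls="--")
    ax.set_xlabel("mean live intensity + 1")
    ax.set_ylabel("mean dead intensity + 1")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_intensity_comparison(
    records: pd.DataFrame, comparison: IntensityComparison, ax=None
):
    """Violin plot of a per-cell stain intensity split by ploidy class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    col = f"mean_{comparison.channel}"
    groups = [comparison.group_b, comparison.group_a]
    data = [
        np.log10(records.loc[records["ploidy_class"] == g, col].dropna() + 1)
        for g in groups
    ]
    parts = ax.violinplot(data, showmedians=True)
    for body, color in zip(parts["bodies"], ("black", "red")):
        body.set_facecolor(color)
    ax.set_xticks([1, 2], groups)
    ax.set_ylabel(f"log10({comparison.channel} intensity + 1)")
    ax.set_title(f"p = {comparison.pvalue:.2e} ({comparison.method})", fontsize=9)
    return ax
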