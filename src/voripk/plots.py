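"""Plotting helpers for model diagnostics and dose simulations.

All functions return the matplotlib Figure so callers can save or embed
it; nothing here touches a display backend.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from scipy import stats  # noqa: E402


def concentration_time_plot(doses, p, t_max: float = 72.0, n: int = 400):
    """Concentration-time profile of a dose history under the linear
    one-compartment model."""
    from .pk import superpose

    t = np.linspace(0.0, t_max, n)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(t, superpose(doses, t, p), lw=1.5)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ug/mL)")
    return fig


def gof_panel(table: pd.DataFrame):
    """Four-panel goodness of fit: DV vs PRED, DV vs IPRED, CWRES vs
    PRED, CWRES vs time after dose."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, xcol, ycol in ((axes[0, 0], "pred", "dv"),
                           (axes[0, 1], "ipred", "dv")):
        ax.plot(table[xcol], table[ycol], "o", ms=3, alpha=0.6)
        lim = max(table[xcol].max(), table[ycol].max()) * 1.05
        ax.plot([0, lim], [0, lim], "k-", lw=0.8)
        ax.set_xlabel(f"{xcol.upper()} (ug/mL)")
        ax.set_ylabel("DV (ug/mL)")
    for ax, xcol in ((axes[1, 0], "pred"), (axes[1, 1], "time_after_dose")):
        ax.plot(table[xcol], table["cwres"], "o", ms=3, alpha=0.6)
        ax.axhline(0, color="k", lw=0.8)
        for y in (-2, 2):
            ax.axhline(y, color="k", lw=0.6, ls="--")
        ax.set_xlabel("PRED (ug/mL)" if xcol == "pred"
                      else "time after dose (h)")
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    return fig


def npde_panel(report, table: pd.DataFrame | None = None):
    """Four-panel NPDE summary: Q-Q plot, histogram, NPDE vs time after
    dose and vs population prediction (when a residual table is given)."""
    values = np.sort(report.npde)
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    qq = stats.norm.ppf((np.arange(values.size) + 0.5) / values.size)
    axes[0, 0].plot(qq, values, "o", ms=3)
    axes[0, 0].plot(qq, qq, "k-", lw=0.8)
    axes[0, 0].set_xlabel("theoretical quantile")
    axes[0, 0].set_ylabel("NPDE")
    axes[0, 1].hist(values, bins=20, density=True, alpha=0.7)
    xs = np.linspace(-3.5, 3.5, 200)
    axes[0, 1].plot(xs, stats.norm.pdf(xs), "k-", lw=0.8)
    axes[0, 1].set_xlabel("NPDE")
    for ax, col, label in ((axes[1, 0], "time_after_dose",
                            "time after dose (h)"),
                           (axes[1, 1], "pred", "PRED (ug/mL)")):
        if table is not None and col in table:
            ax.plot(table[col], report.npde, "o", ms=3, alpha=0.6)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_xlabel(label)
        ax.set_ylabel("NPDE")
    fig.tight_layout()
    return fig


def vpc_plot(result):
    """Observed percentiles against simulated confidence bands, one panel
    per stratum."""
    bands = result.bands
    fig, axes = plt.subplots(1, max(len(bands), 1),
                             figsize=(5 * max(len(bands), 1), 4),
                             squeeze=False)
    for ax, band in zip(axes[0], bands):
        for p in result.percentiles:
            ax.fill_between(band.bin_mid, band.sim_low[p], band.sim_high[p],
                            alpha=0.25)
            ax.plot(band.bin_mid, band.observed[p], "o-", ms=4,
                    label=f"obs {p}th")
        ax.set_title(band.stratum)
        ax.set_xlabel("time after dose (h)")
        ax.set_ylabel("concentration (ug/mL)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def pta_plot(grid: pd.DataFrame, phenotype: str):
    """Stacked attainment fractions per dose and CRP stratum for one
    phenotype, with the 0.5-5.0 ug/mL window in mind."""
    sub = grid[grid["phenotype"] == phenotype]
    crps = sorted(sub["crp"].unique())
    fig, axes = plt.subplots(1, len(crps), figsize=(3 * len(crps), 4),
                             sharey=True, squeeze=False)
    for ax, crp in zip(axes[0], crps):
        g = sub[sub["crp"] == crp].sort_values("dose")
        x = np.arange(len(g))
        ax.bar(x, g["subtherapeutic"], label="<0.5")
        ax.bar(x, g["therapeutic"], bottom=g["subtherapeutic"],
               label="0.5-5.0")
        ax.bar(x, g["toxic"],
               bottom=g["subtherapeutic"] + g["therapeutic"], label=">5.0")
        ax.set_xticks(x, [f"{d:g}" for d in g["dose"]])
        ax.set_xlabel("dose (mg q12h)")
        ax.set_title(f"CRP {crp:g} mg/L")
    axes[0, 0].set_ylabel("fraction of patients")
    axes[0, -1].legend(fontsize=8)
    fig.suptitle(f"CYP2C19 {phenotype}")
    fig.tight_layout()
    return fig
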