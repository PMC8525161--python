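"""Matplotlib views of trajectories, indicator series and risk curves.

Each function returns the Figure; callers decide where to save it.  The
CLI writes vector graphics (SVG) and always emits the underlying numbers
as CSV alongside, so figures are never the only record.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .lpi import EnsembleLPI
from .risk import CATEGORIES, CategoryThresholds, ExtinctionRiskCurve, RLISeries
from .simulate import AbundanceTrajectory

_CATEGORY_COLORS = {
    "LC": "#4daf4a",
    "VU": "#ffd92f",
    "EN": "#ff7f00",
    "CR": "#e41a1c",
    "EX": "#555555",
}


def plot_trajectory(
    traj: AbundanceTrajectory, thresholds: CategoryThresholds | None = None
):
    """Spaghetti plot of every species' abundance; optional category cutoffs."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(traj.years, traj.abundances.T, lw=0.8, alpha=0.7)
    if thresholds is not None:
        for label, a in [
            ("CR", thresholds.A_CR), ("EN", thresholds.A_EN), ("VU", thresholds.A_VU)
        ]:
            ax.axhline(a, color=_CATEGORY_COLORS[label], lw=1.5, label=label)
        ax.legend(title="threshold", loc="upper right", fontsize=8)
        ax.set_yscale("symlog", linthresh=1)
    ax.set_xlabel("year")
    ax.set_ylabel("abundance")
    ax.set_title("Zero-sum ecological drift")
    fig.tight_layout()
    return fig


def plot_ensemble_lpi(ens: EnsembleLPI):
    """Mean LPI with its 95% percentile envelope across replicates."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(ens.years, ens.lo95, ens.hi95, alpha=0.3, label="95% envelope")
    ax.plot(ens.years, ens.mean, lw=2, label="mean")
    ax.axhline(1.0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("year")
    ax.set_ylabel("Living Planet Index")
    ax.set_title(f"LPI under neutral drift ({ens.n_replicates} replicates)")
    ax.legend()
    fig.tight_layout()
    return fig


def plot_risk_curves(
    curve: ExtinctionRiskCurve, thresholds: CategoryThresholds | None = None
):
    """Smoothed extinction probability vs abundance, one line per horizon."""
    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.arange(1, curve.J + 1)
    for h in curve.horizons:
        ax.plot(grid, curve.p_smooth[h][1:], label=f"{h} years")
    if thresholds is not None:
        for label, a in [
            ("CR", thresholds.A_CR), ("EN", thresholds.A_EN), ("VU", thresholds.A_VU)
        ]:
            ax.axvline(a, color=_CATEGORY_COLORS[label], lw=1.2, ls="--", label=label)
    ax.set_xscale("log")
    ax.set_xlabel("abundance")
    ax.set_ylabel("extinction probability")
    ax.set_title("Extinction risk vs abundance")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_category_proportions(props: pd.DataFrame):
    """Stacked per-year fractions of species per threat category."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.stackplot(
        props.index,
        [props[c] for c in CATEGORIES],
        labels=CATEGORIES,
        colors=[_CATEGORY_COLORS[c] for c in CATEGORIES],
        alpha=0.9,
    )
    ax.set_xlabel("year")
    ax.set_ylabel("fraction of species")
    ax.set_ylim(0, 1)
    ax.set_title("Threat categories through time")
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    return fig


def plot_rli(series: RLISeries, lo: np.ndarray | None = None,
             hi: np.ndarray | None = None):
    """Red List Index through time, with an optional ensemble envelope."""
    fig, ax = plt.subplots(figsize=(6, 4))
    if lo is not None and hi is not None:
        ax.fill_between(series.years, lo, hi, alpha=0.3, label="95% envelope")
    ax.plot(series.years, series.rli, lw=2, label="RLI")
    ax.set_xlabel("year")
    ax.set_ylabel("Red List Index")
    ax.set_ylim(0, 1.02)
    ax.set_title("Red List Index under neutral drift")
    ax.legend()
    fig.tight_layout()
    return fig
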