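"""Plots for damage curves and Rosenthal-Henderson series.

Conventions follow the field's B-factor plots: resolution on an inverse
square scale against ln(particle number); damage curves as value +- SE
over depth-bin midpoints with the fitted exponential decay overlaid.
"""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .damage_curves import DecayFit, DepthPoint

__all__ = ["plot_damage_curve", "plot_bfactor_series"]


def plot_damage_curve(
    points: list[DepthPoint],
    fit: DecayFit | None,
    path: str | os.PathLike,
    ylabel: str = "B-factor ratio",
) -> None:
    """Damage curve over depth with the weighted exponential-decay fit."""
    x = np.array([p.x_nm for p in points])
    y = np.array([p.value for p in points])
    se = np.array([p.se for p in points])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(x, y, yerr=se, fmt="o", ms=4, capsize=2, color="k", lw=1)
    if fit is not None and fit.converged:
        xs = np.linspace(x.min(), x.max(), 200)
        ax.plot(xs, fit.predict(xs), "-", color="tab:red", lw=1.2)
        ax.annotate(
            f"$y = {fit.A:.3g}\\,e^{{-{fit.k:.3g}x}} + {fit.c:.3g}$\n"
            f"$R^2 = {fit.r_squared:.2f}$",
            xy=(0.55, 0.75),
            xycoords="axes fraction",
            fontsize=8,
        )
    ax.set_xlabel("distance from milling surface (nm)")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_bfactor_series(series: pd.DataFrame, path: str | os.PathLike) -> None:
    """Per-group resolution vs particle number on the B-factor plot scale."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for group, sub in series.groupby("group"):
        agg = sub.groupby("n_particles")["resolution_A"].agg(["mean", "sem"])
        ax.errorbar(
            np.log(agg.index.to_numpy(dtype=float)),
            1.0 / agg["mean"] ** 2,
            yerr=2 * agg["sem"] / agg["mean"] ** 3,
            fmt="o-",
            ms=3,
            lw=0.8,
            label=str(group),
        )
    ax.set_xlabel("ln(particle number)")
    ax.set_ylabel(r"$1/\mathrm{resolution}^2$ ($\mathrm{\AA}^{-2}$)")
    ax.legend(fontsize=6, ncols=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
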