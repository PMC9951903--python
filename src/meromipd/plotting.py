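"""Diagnostic plots: VPC bands, goodness-of-fit scatter, PE% boxes, profiles."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import DEFAULT_IQR_BOUND, REFERENCE_LINE
from .vpc import VPCBands

__all__ = ["plot_vpc", "plot_gof", "plot_pe_boxes", "plot_profiles"]


def plot_vpc(bands: VPCBands, stratum: str = "all", ax: Optional[plt.Axes] = None):
    """Observed percentile lines against simulated confidence bands per bin."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    table = bands.table
    table = table[table["stratum"] == stratum]
    mid = 0.5 * (table["bin_low"] + table["bin_high"])
    for tag, color in (("p5", "tab:purple"), ("p50", "tab:red"), ("p95", "tab:purple")):
        if f"sim_{tag}_lo" not in table:
            continue
        ax.fill_between(mid, table[f"sim_{tag}_lo"], table[f"sim_{tag}_hi"],
                        alpha=0.25, color=color, linewidth=0)
        ax.plot(mid, table[f"obs_{tag}"], color=color, marker="o",
                label=f"observed {tag}")
    ax.set_xlabel("time after end of infusion (h)")
    ax.set_ylabel("concentration (mg/L)")
    ax.set_title(f"VPC ({stratum}, {bands.n_replicates} replicates)")
    ax.legend(fontsize=8)
    return ax


def plot_gof(gof: pd.DataFrame, kind: str = "pred", ax: Optional[plt.Axes] = None):
    """Predicted-versus-observed scatter with the unity line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    col = "c_pred" if kind == "pred" else "c_ipred"
    ax.scatter(gof["c_obs"], gof[col], s=12, alpha=0.6)
    lim = max(gof["c_obs"].max(), gof[col].max()) * 1.05
    ax.plot([0, lim], [0, lim], "k--", linewidth=1)
    ax.set_xlabel("observed (mg/L)")
    ax.set_ylabel(f"{'population' if kind == 'pred' else 'individual'} predicted (mg/L)")
    return ax


def plot_pe_boxes(pe_by_k: dict, ax: Optional[plt.Axes] = None):
    """PE% distributions per support count with the ±20/±30% reference lines."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ks = sorted(pe_by_k)
    ax.boxplot([pe_by_k[k] for k in ks], tick_labels=[str(k) for k in ks],
               showfliers=False)
    for bound, style in ((REFERENCE_LINE, ":"), (DEFAULT_IQR_BOUND, "--")):
        ax.axhline(bound, color="grey", linestyle=style, linewidth=1)
        ax.axhline(-bound, color="grey", linestyle=style, linewidth=1)
    ax.set_xlabel("concentrations used for conditioning (k)")
    ax.set_ylabel("prediction error (%)")
    return ax


def plot_profiles(profiles: pd.DataFrame, ax: Optional[plt.Axes] = None):
    """Concentration-time curves, one line per (model, scenario)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for (model, scenario), sub in profiles.groupby(["model", "scenario"]):
        ax.plot(sub["time"], sub["concentration"], label=f"{model}/{scenario}",
                linewidth=1)
    ax.set_xlabel("time since first dose (h)")
    ax.set_ylabel("concentration (mg/L)")
    if profiles[["model", "scenario"]].drop_duplicates().shape[0] <= 12:
        ax.legend(fontsize=7)
    return ax
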