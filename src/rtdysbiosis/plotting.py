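"""Static figures: MCPI trajectories and LME margin curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_mcpi_trajectory(series: pd.DataFrame, tests: pd.DataFrame, path) -> None:
    """Group-mean MCPI +/- s.e. per timepoint; asterisks mark p < 0.05."""
    order = list(tests["timepoint"]) if len(tests) else list(
        dict.fromkeys(series["timepoint"])
    )
    fig, ax = plt.subplots(figsize=(6, 4))
    for tox, label, color in ((1, "toxicity", "C3"), (0, "no toxicity", "C0")):
        sub = series[series["toxicity"] == tox]
        means = [sub.loc[sub["timepoint"] == t, "mcpi"].mean() for t in order]
        sems = [
            sub.loc[sub["timepoint"] == t, "mcpi"].sem(ddof=1) for t in order
        ]
        ax.errorbar(range(len(order)), means, yerr=sems, label=label, color=color,
                    marker="o", capsize=3)
    if len(tests):
        top = series["mcpi"].max()
        for i, t in enumerate(order):
            row = tests[tests["timepoint"] == t]
            if len(row) and row["p_value"].iloc[0] < 0.05:
                ax.annotate("*", (i, top), ha="center", fontsize=14)
    ax.set_xticks(range(len(order)), order)
    ax.set_ylabel("MCPI")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_margins(margins: pd.DataFrame, taxon: str, path) -> None:
    """Per-group predictive-margin curves with 95% bands; asterisks mark
    significant contrasts (p < 0.05)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    d = margins["day"].to_numpy()
    for suffix, label, color in (("1", "toxicity", "C3"), ("0", "no toxicity", "C0")):
        m = margins[f"margin_{suffix}"].to_numpy()
        se = margins[f"se_{suffix}"].to_numpy()
        ax.plot(d, m, label=label, color=color)
        ax.fill_between(d, m - 1.96 * se, m + 1.96 * se, color=color, alpha=0.2)
    sig = margins["p_value"].to_numpy() < 0.05
    if sig.any():
        top = np.nanmax(margins[["margin_0", "margin_1"]].to_numpy())
        ax.plot(d[sig], np.full(sig.sum(), top * 1.05), "k*", markersize=8)
    ax.set_xlabel("days since RT start")
    ax.set_ylabel(f"{taxon} abundance")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
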