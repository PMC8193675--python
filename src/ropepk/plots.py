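"""Plot helpers for the standard model-evaluation figures.

Thin matplotlib wrappers kept separate from the computation: every function
takes the already-computed result object and an output path, so the figures
are a pure rendering of numbers the pipeline has written to CSV anyway.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_pc_vpc(vpc, path, log_scale: bool = False) -> None:
    """Observed percentile curves over the simulated confidence bands."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = ["#c44e52", "#4c72b0", "#c44e52"]
    for j, q in enumerate(vpc.percentiles):
        ax.fill_between(vpc.bin_mid, vpc.sim_lower[:, j], vpc.sim_upper[:, j],
                        alpha=0.25, color=colors[j % 3], linewidth=0)
        ax.plot(vpc.bin_mid, vpc.sim_median[:, j], "--", color=colors[j % 3],
                label=f"simulated p{q:g}" if j < 3 else None)
        ax.plot(vpc.bin_mid, vpc.observed[:, j], "-", color="0.2",
                label="observed" if j == 0 else None)
    ax.set_xlabel("time after dose [h]")
    ax.set_ylabel("prediction-corrected concentration [ng/ml]")
    if log_scale:
        ax.set_yscale("log")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gof(gof_table, path) -> None:
    """Four-panel goodness-of-fit: DV vs PRED/IPRED, CWRES vs time/PRED."""
    fig, axes = plt.subplots(2, 2, figsize=(8, 7))
    dv, pred, ipred = gof_table["dv"], gof_table["pred"], gof_table["ipred"]
    for ax, x, xlab in ((axes[0, 0], pred, "PRED"), (axes[0, 1], ipred, "IPRED")):
        ax.plot(x, dv, ".", ms=3, alpha=0.5)
        lim = [0, max(dv.max(), x.max()) * 1.05]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel(f"{xlab} [ng/ml]")
        ax.set_ylabel("observed [ng/ml]")
    for ax, x, xlab in ((axes[1, 0], gof_table["time"], "time [h]"),
                        (axes[1, 1], pred, "PRED [ng/ml]")):
        ax.plot(x, gof_table["cwres"], ".", ms=3, alpha=0.5)
        ax.axhline(0.0, color="k", ls="--", lw=0.8)
        ax.set_xlabel(xlab)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_aucss_distributions(summaries, path) -> None:
    """Overlaid steady-state exposure densities with 10th/90th percentile marks."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    colors = {"Caucasian": "#c44e52", "Chinese": "#4c72b0"}
    for s in summaries:
        color = colors.get(s.label, "0.4")
        vals = np.log10(s.auc_ss)
        hist, edges = np.histogram(vals, bins=40, density=True)
        mids = 0.5 * (edges[1:] + edges[:-1])
        ax.fill_between(10 ** mids, 0, hist, alpha=0.3, color=color,
                        label=f"{s.label} {s.dose:g} ug")
        for q in (10.0, 90.0):
            ax.axvline(s.percentiles[q], color=color, ls="--", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("steady-state AUC over one interval [ng*h/ml]")
    ax.set_ylabel("density (log scale)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
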