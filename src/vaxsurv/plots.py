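"""Diagnostic plots mirroring the four standard surveillance-evaluation views:
estimate-vs-SE scatters with the p<0.05 boundary, fitted systematic-error
distributions, type 1/2 error bars before and after calibration, and
months-to-sensitivity tiles.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .calibration import fit_null


def plot_estimates(records: pd.DataFrame, path, max_panels: int = 8) -> None:
    """Estimate vs SE scatter per (design, variant); below the dashed line p < .05."""
    groups = list(records[records["estimable"]].groupby(["design", "variant"]))[:max_panels]
    n = max(len(groups), 1)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), squeeze=False, sharey=True)
    for ax, ((design, variant), g) in zip(axes[0], groups):
        neg = g[g["true_effect_size"] == 1.0]
        ax.scatter(neg["log_estimate"], neg["se"], s=8, alpha=0.6)
        xs = np.linspace(*ax.get_xlim(), 50)
        ax.plot(xs, np.maximum(xs, 1e-9) / stats.norm.ppf(0.95), "r--", lw=1)
        ax.set_title(f"{design}\n{variant}", fontsize=8)
        ax.set_xlabel("log estimate")
    axes[0][0].set_ylabel("standard error")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_null_distributions(records: pd.DataFrame, path, max_panels: int = 8) -> None:
    """Fitted Gaussian systematic-error densities per (design, variant)."""
    groups = list(records.groupby(["design", "variant"]))[:max_panels]
    n = max(len(groups), 1)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 2.5), squeeze=False, sharex=True)
    xs = np.linspace(-2, 2, 200)
    for ax, ((design, variant), g) in zip(axes[0], groups):
        neg = g[(g["true_effect_size"] == 1.0) & g["estimable"]]
        if len(neg) >= 2:
            null = fit_null(neg["log_estimate"], neg["se"])
            sd = max(null.tau, 1e-3)
            ax.fill_between(xs, stats.norm.pdf(xs, null.mu, sd), color="tab:red", alpha=0.5)
            ax.axvline(0, color="k", lw=0.5)
        ax.set_title(f"{design}\n{variant}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_type12(performance: pd.DataFrame, path) -> None:
    """Type 1 (and available type 2) error bars, pre vs post calibration."""
    fig, ax = plt.subplots(figsize=(8, 0.5 * len(performance) + 1.5))
    y = np.arange(len(performance))
    labels = performance["design"] + "/" + performance["variant"]
    ax.barh(y + 0.2, performance["type1"], height=0.35, label="type 1 (uncalibrated)")
    ax.barh(y - 0.2, performance["type1_calibrated"], height=0.35, label="type 1 (calibrated)")
    ax.axvline(0.05, color="k", ls="--", lw=1)
    ax.set_yticks(y, labels, fontsize=7)
    ax.set_xlabel("error rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_time_to_sensitivity(performance: pd.DataFrame, path) -> None:
    """Tile plot of months to 50% sensitivity by variant and true effect size."""
    cols = [c for c in performance.columns if c.startswith("months_to_50pct")]
    if not cols:
        return
    mat = performance[cols].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(2 + len(cols), 0.4 * len(performance) + 1.5))
    im = ax.imshow(mat, aspect="auto", cmap="viridis_r")
    ax.set_xticks(range(len(cols)), [c.rsplit("rr", 1)[-1] for c in cols])
    ax.set_yticks(
        range(len(performance)), performance["design"] + "/" + performance["variant"], fontsize=7
    )
    ax.set_xlabel("true effect size")
    fig.colorbar(im, label="months to 50% sensitivity")
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            txt = "never" if np.isnan(mat[i, j]) else f"{mat[i, j]:.0f}"
            ax.text(j, i, txt, ha="center", va="center", fontsize=7, color="w")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def write_all_plots(records: pd.DataFrame, performance: pd.DataFrame, directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [
        directory / "estimates_vs_se.png",
        directory / "systematic_error.png",
        directory / "type1_type2.png",
        directory / "time_to_sensitivity.png",
    ]
    plot_estimates(records, paths[0])
    plot_null_distributions(records, paths[1])
    plot_type12(performance, paths[2])
    plot_time_to_sensitivity(performance, paths[3])
    return paths
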