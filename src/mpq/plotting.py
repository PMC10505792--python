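"""Figure-style views of pipeline CSV outputs.

Plots are pure views: everything drawn here is regenerable from the CSVs
alone.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd


def save_profile_plot(aggregates: dict, path) -> str:
    """Mean radial profile per condition with an SD ribbon."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, agg in aggregates.items():
        x = (agg.bin_edges[:-1] + agg.bin_edges[1:]) / 2.0
        ax.plot(x, agg.mean, label=cond)
        ax.fill_between(x, agg.mean - agg.sd, agg.mean + agg.sd, alpha=0.25)
    ax.set_xlabel("distance to colony center (µm)")
    ax.set_ylabel("normalized nuclear SMAD2/3 (a.u.)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def save_band_scatter(bands: pd.DataFrame, path) -> str:
    """Per-colony center- and edge-band means by condition."""
    fig, axes = plt.subplots(1, 2, figsize=(7, 4), sharey=True)
    conds = sorted(bands["condition"].dropna().unique())
    for ax, col, title in zip(
        axes, ["center_mean", "edge_mean"], ["center band", "edge band"]
    ):
        for i, cond in enumerate(conds):
            v = bands.loc[bands["condition"] == cond, col].dropna()
            ax.plot([i] * len(v), v, "o", alpha=0.6, ms=4)
            if len(v):
                ax.hlines(v.mean(), i - 0.25, i + 0.25, color="k")
        ax.set_xticks(range(len(conds)), conds)
        ax.set_title(title)
    axes[0].set_ylabel("mean nuclear SMAD2/3 (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def save_domain_plot(domains: pd.DataFrame, frac_cols: list[str], path) -> str:
    """Per-neuruloid marker area fractions by condition."""
    fig, axes = plt.subplots(1, len(frac_cols), figsize=(3 * len(frac_cols), 4))
    if len(frac_cols) == 1:
        axes = [axes]
    conds = sorted(domains["condition"].dropna().unique())
    for ax, col in zip(axes, frac_cols):
        for i, cond in enumerate(conds):
            v = domains.loc[domains["condition"] == cond, col]
            ax.plot([i] * len(v), v, "o", alpha=0.6, ms=4)
            if len(v):
                ax.hlines(v.mean(), i - 0.25, i + 0.25, color="k")
        ax.set_xticks(range(len(conds)), conds)
        ax.set_title(col.replace("_frac", ""))
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("area fraction of DAPI")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
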