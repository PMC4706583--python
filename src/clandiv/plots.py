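"""Optional figures: per-rank diversity heatmaps and variance-partition pies.

These mirror the usual presentation of taxonomy-stratified diversity — one
heatmap column per rank with cell colour = clan mean p-distance (blank where
unavailable), and one pie per taxonomy bifurcation split into inter-clan
(dark) and intra-clan (light) variance.  All acceptance-relevant numbers
live in the TSVs; the figures are conveniences.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def rank_heatmap(table: pd.DataFrame, path: str | Path) -> None:
    """One column per rank; one cell per clan, colour = mean p-distance."""
    ranks = list(dict.fromkeys(table["rank"]))
    fig, axes = plt.subplots(
        1, len(ranks), figsize=(2.2 * len(ranks), 6), squeeze=False
    )
    for ax, rank in zip(axes[0], ranks):
        sub = table[table["rank"] == rank].reset_index(drop=True)
        vals = sub["mean_p"].to_numpy(dtype=float).reshape(-1, 1)
        im = ax.imshow(vals, cmap="viridis", vmin=0, vmax=1, aspect="auto")
        ax.set_title(rank, fontsize=9)
        ax.set_yticks(range(len(sub)))
        ax.set_yticklabels(sub["taxon"], fontsize=6)
        ax.set_xticks([])
    fig.colorbar(im, ax=axes[0], shrink=0.6, label="mean p-distance")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def partition_pies(pframe: pd.DataFrame, path: str | Path) -> None:
    """One pie per computed bifurcation: inter-clan dark, intra-clan light."""
    ok = pframe[pframe["status"] == "ok"].reset_index(drop=True)
    n = max(len(ok), 1)
    ncol = min(n, 6)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(2.0 * ncol, 2.2 * nrow), squeeze=False
    )
    flat = [ax for row in axes for ax in row]
    for ax in flat:
        ax.axis("off")
    for ax, (_, row) in zip(flat, ok.iterrows()):
        ax.pie(
            [row["pct_inter"], row["pct_intra"]],
            colors=["#20435c", "#a8d0e6"],
            startangle=90,
        )
        ax.set_title(
            f"{row['taxon']}\ninter {row['pct_inter']:.1f}%", fontsize=7
        )
        ax.axis("equal")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
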