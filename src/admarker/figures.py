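"""Optional SVG figures for the exploratory outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["volcano_figure", "pca_figure", "heatmap_figure"]


def volcano_figure(volcano_df: pd.DataFrame, path, p_threshold: float = 0.05) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    df = volcano_df.dropna(subset=["log2_fc"])
    sig = df["p_value"] < p_threshold
    ax.scatter(df.loc[~sig, "log2_fc"], -np.log10(df.loc[~sig, "p_value"]),
               s=10, c="grey", alpha=0.6)
    ax.scatter(df.loc[sig, "log2_fc"], -np.log10(df.loc[sig, "p_value"]),
               s=14, c="crimson")
    ax.axhline(-np.log10(p_threshold), ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (responders / non-responders)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def pca_figure(scores: pd.DataFrame, responder_flags, path) -> None:
    flags = np.asarray(responder_flags).astype(bool)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(scores.loc[~flags, "PC1"], scores.loc[~flags, "PC2"],
               c="grey", label="non-responder")
    ax.scatter(scores.loc[flags, "PC1"], scores.loc[flags, "PC2"],
               c="crimson", label="responder")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def heatmap_figure(matrix: pd.DataFrame, row_order, col_order, path) -> None:
    from .explore import zscore_matrix

    z = zscore_matrix(matrix).loc[row_order, [c for c in col_order]]
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xlabel("biomarker")
    ax.set_ylabel("patient")
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
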