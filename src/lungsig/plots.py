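"""Figure helpers: PCA score scatter by run, PVCA bar chart."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .decompose import PcaResult, PvcaResult

RUN_COLORS = {1: "tab:orange", 2: "tab:cyan", 3: "navy",
              4: "gold", 5: "darkgreen", 6: "orchid"}


def plot_pca_runs(result: PcaResult, annotation: pd.DataFrame, path: str | Path,
                  title: str = "") -> Path:
    """First two PC scores, one marker per array, colored by processing run."""
    fig, ax = plt.subplots(figsize=(5, 4))
    scores = result.scores
    runs = annotation.loc[scores.index, "run"]
    for run in sorted(runs.unique()):
        sel = (runs == run).to_numpy()
        ax.scatter(scores.iloc[sel, 0], scores.iloc[sel, 1], s=18,
                   color=RUN_COLORS.get(int(run), "gray"), label=f"run {run}")
    ax.set_xlabel(f"PC1 ({100 * result.proportions[0]:.1f}%)")
    if scores.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({100 * result.proportions[1]:.1f}%)")
    ax.legend(fontsize=7)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_pvca_bars(result: PvcaResult, path: str | Path, title: str = "") -> Path:
    """Weighted proportion of variance per factor, largest first."""
    items = sorted(result.proportions.items(), key=lambda kv: -kv[1])
    labels = [k for k, _ in items]
    values = [100 * v for _, v in items]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(range(len(items)), values, color="steelblue")
    ax.set_xticks(range(len(items)))
    ax.set_xticklabels(labels, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("weighted proportion of variance (%)")
    ax.set_title(title or f"PVCA ({result.n_components} PCs, "
                          f"threshold {result.threshold:.0%})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
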