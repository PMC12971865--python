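"""Optional figure outputs (elbow curve, metric box plots, importances)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from gazeskill.metrics import FEATURE_COLUMNS


def _axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def elbow_plot(wcss_curve: Mapping[int, float], path: str | Path) -> None:
    plt = _axes()
    ks = sorted(wcss_curve)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ks, [wcss_curve[k] for k in ks], marker="o")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("WCSS")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def metric_box_plots(table: pd.DataFrame, labels: Sequence, path: str | Path) -> None:
    plt = _axes()
    df = table.copy()
    df["_level"] = list(labels)
    cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    fig, axes = plt.subplots(2, 3, figsize=(11, 6))
    for ax, col in zip(axes.ravel(), cols):
        df.boxplot(column=col, by="_level", ax=ax)
        ax.set_title(col)
        ax.set_xlabel("")
    fig.suptitle("")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def importance_plot(importances: pd.Series, path: str | Path) -> None:
    plt = _axes()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    importances.sort_values().plot.barh(ax=ax)
    ax.set_xlabel("Gini importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
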