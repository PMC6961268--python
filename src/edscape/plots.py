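"""Minimal bubble-chart reporting for editing tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def bubble_chart(
    table: pd.DataFrame,
    x: str,
    y: str,
    color: str = "mean",
    size: str = "n_replicates",
    out_path=None,
):
    """Bubble chart: color = editing level / ratio, size = data volume.

    Mirrors the usual per-site-by-stratum layout of editing-level tables:
    one bubble per (x, y) cell, colored by ``color`` and scaled by
    ``size``.  Returns the Matplotlib figure; saves PNG when ``out_path``
    is given.
    """
    df = table.dropna(subset=[color]).copy()
    xs = {v: i for i, v in enumerate(sorted(df[x].unique()))}
    ys = {v: i for i, v in enumerate(sorted(df[y].unique()))}
    sizes = df[size].to_numpy(dtype=float) if size in df else np.full(len(df), 30.0)
    smax = sizes.max() if len(sizes) and sizes.max() > 0 else 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * len(xs) + 2), max(3, 0.35 * len(ys) + 1.5))
    )
    sc = ax.scatter(
        [xs[v] for v in df[x]],
        [ys[v] for v in df[y]],
        c=df[color],
        s=40 + 200 * sizes / smax,
        cmap="coolwarm",
        edgecolors="k",
        linewidths=0.3,
    )
    ax.set_xticks(list(xs.values()), list(xs.keys()), rotation=45, ha="right")
    ax.set_yticks(list(ys.values()), list(ys.keys()))
    fig.colorbar(sc, ax=ax, label=color)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
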