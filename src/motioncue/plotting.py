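"""Optional figures: scalp accuracy topographies and confusion heatmaps.

Matplotlib is imported lazily so the core pipeline has no plotting
dependency.  Color scales are centered on chance, so warm colors always mean
above-chance decoding regardless of the number of classes.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import montage


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_topography(
    electrodes: List[str],
    values: np.ndarray,
    chance: float,
    title: str = "",
    significant: Optional[np.ndarray] = None,
    ax=None,
):
    """Scatter accuracy over schematic head coordinates, chance-centered."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pos = montage.positions(electrodes)
    span = max(np.abs(np.asarray(values) - chance).max(), 1e-3)
    sc = ax.scatter(
        pos[:, 0], pos[:, 1], c=values, s=250, cmap="RdYlBu_r",
        vmin=chance - span, vmax=chance + span, edgecolors="k",
    )
    for (x, y), lab in zip(pos, electrodes):
        ax.annotate(lab, (x, y), ha="center", va="center", fontsize=5)
    if significant is not None:
        for (x, y), sig in zip(pos, significant):
            if sig:
                ax.annotate("*", (x, y + 0.10), ha="center", color="k", fontsize=12)
    head = plt.Circle((0, 0), 1.15, fill=False, color="k")
    ax.add_patch(head)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title, fontsize=9)
    plt.colorbar(sc, ax=ax, shrink=0.7, label="accuracy")
    return ax


def plot_confusion(confusion: np.ndarray, chance: float, title: str = "", ax=None):
    """Heatmap of classified (rows) vs true (columns) class counts."""
    plt = _mpl()
    if ax is None:
        _, ax = plt.subplots(figsize=(3.5, 3))
    rates = confusion / max(confusion.sum(axis=0).max(), 1)
    span = max(np.abs(rates - chance).max(), 1e-3)
    im = ax.imshow(rates, cmap="RdYlBu_r", vmin=chance - span, vmax=chance + span,
                   origin="upper")
    ax.set_xlabel("true class")
    ax.set_ylabel("classified class")
    ax.set_title(title, fontsize=9)
    plt.colorbar(im, ax=ax, shrink=0.8)
    return ax


def render_report(tables_dir: Path, out_dir: Path) -> List[Path]:
    """Render one topography PNG per significance table in a run directory."""
    plt = _mpl()
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for table in sorted(Path(tables_dir).glob("significance_*.tsv")):
        df = pd.read_csv(table, sep="\t")
        known = df["electrode"].isin(montage.ELECTRODE_POSITIONS).to_numpy()
        df = df[known]
        if df.empty:
            continue
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        plot_topography(
            list(df["electrode"]),
            df["gamma_hat"].to_numpy(),
            chance=float(df["chance"].iloc[0]),
            significant=df["holm_significant"].to_numpy(),
            title=table.stem.replace("significance_", ""),
            ax=ax,
        )
        p = out_dir / f"{table.stem}.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written
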