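"""Pie-chart rendering of per-compound potency slices (ToxPi style)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def toxpi_pie(scaled_row: pd.Series, title: str | None = None, ax=None):
    """Draw one compound's profile as equal-angle wedges with radius = slice.

    Each endpoint occupies the same angular sector; how far the wedge
    extends from the origin encodes the scaled potency (1 = lowest BMC in
    that endpoint across the dataset, 0 = censored).
    """
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    n = len(scaled_row)
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    width = 2 * np.pi / n
    ax.bar(theta, scaled_row.to_numpy(dtype=float), width=width, align="edge",
           edgecolor="white", linewidth=1)
    ax.set_ylim(0, 1)
    ax.set_xticks(theta + width / 2)
    ax.set_xticklabels(scaled_row.index, fontsize=7)
    ax.set_yticklabels([])
    if title:
        ax.set_title(title)
    return ax


def save_toxpi_pies(scaled: pd.DataFrame, out_dir) -> list[Path]:
    """One PNG per compound from a compound x endpoint slice matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for compound, row in scaled.iterrows():
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(3.2, 3.2))
        toxpi_pie(row, title=str(compound), ax=ax)
        path = out / f"toxpi_{compound}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
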