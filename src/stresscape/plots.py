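"""Figure helpers: importance dot-plots and classified stress maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .raster import GridRaster

CLASS_COLORS = {1: "#2c7bb6", 2: "#ffffbf", 3: "#d7191c"}  # low/mod/high


def importance_dotplot(
    importance: pd.DataFrame, path: str | Path, title: str = ""
) -> None:
    """Side-by-side %IncMSE and IncNodePurity dot plot, one row per
    variable, most important on top."""
    frame = importance.sort_values("pct_inc_mse")
    fig, axes = plt.subplots(
        1, 2, figsize=(8, 0.3 * len(frame) + 1.5), sharey=True
    )
    ypos = np.arange(len(frame))
    for ax, col, label in (
        (axes[0], "pct_inc_mse", "%IncMSE"),
        (axes[1], "inc_node_purity", "IncNodePurity"),
    ):
        ax.plot(frame[col], ypos, "o", color="#333333")
        ax.set_yticks(ypos)
        ax.set_yticklabels(frame["variable"])
        ax.set_xlabel(label)
        ax.grid(axis="y", linestyle=":", alpha=0.6)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def class_map(classified: GridRaster, path: str | Path, title: str = "") -> None:
    """Map of the low/moderate/high classification; nodata in grey."""
    vals = classified.values
    rgb = np.full((*vals.shape, 3), 0.8)
    for code, color in CLASS_COLORS.items():
        hexv = color.lstrip("#")
        rgb[vals == code] = [int(hexv[i:i + 2], 16) / 255 for i in (0, 2, 4)]
    fig, ax = plt.subplots(figsize=(6, 6))
    xmin, ymin, xmax, ymax = classified.bounds
    ax.imshow(rgb, extent=(xmin, xmax, ymin, ymax))
    ax.set_xlabel("easting (m)")
    ax.set_ylabel("northing (m)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
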