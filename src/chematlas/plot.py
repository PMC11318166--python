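"""Static scatter export of a chemical map (SVG/PNG via matplotlib)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .validation import clip_color_range


def scatter_map(
    frame: pd.DataFrame,
    path: str | Path,
    color: str | None = None,
    clip: tuple[float, float] | None = None,
    title: str | None = None,
) -> Path:
    """Render the 2D map colored by a column, with optional color-range clipping."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 6))
    if color is not None and color in frame.columns and pd.api.types.is_numeric_dtype(frame[color]):
        vals = frame[color].to_numpy(dtype=float)
        if clip is not None:
            vals = clip_color_range(vals, *clip)
        sc = ax.scatter(frame["x"], frame["y"], c=vals, s=12, cmap="RdYlBu_r", alpha=0.8)
        fig.colorbar(sc, ax=ax, label=color)
    elif color is not None and color in frame.columns:
        for key, grp in frame.groupby(color):
            ax.scatter(grp["x"], grp["y"], s=12, alpha=0.8, label=str(key))
        ax.legend(title=color, fontsize=8)
    else:
        ax.scatter(frame["x"], frame["y"], s=12, alpha=0.8)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
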