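"""Figure and CSV export for biplots, histograms and the leukocyte map."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .histogram import SampleHistogram
from .top_model import LeukocyteMap

__all__ = [
    "export_histogram_csv",
    "export_map_csv",
    "plot_leukocyte_map",
]


def export_histogram_csv(hist: SampleHistogram, path: str | Path) -> None:
    """Write a 1-D or 2-D histogram as a CSV grid (rows = first component)."""
    values = hist.values
    if values.ndim > 2:
        raise ValueError("CSV export supports 1-D and 2-D histograms only")
    pd.DataFrame(np.atleast_2d(values)).to_csv(path, index=False, header=False)


def export_map_csv(lmap: LeukocyteMap, path: str | Path) -> None:
    """Write the F x F weight grid as CSV (rows = first component)."""
    pd.DataFrame(lmap.weights).to_csv(path, index=False, header=False)


def plot_leukocyte_map(
    lmap: LeukocyteMap,
    path: str | Path,
    contours: list[SampleHistogram] | None = None,
    title: str = "leukocyte map",
) -> None:
    """Render the map: red = control-enriched bins, blue = challenged.

    The first base component runs along x; overlaid black vectors are
    the base-model loadings, scaled to the plot. Optional histogram
    contours outline where a given sample's cells sit.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    w = lmap.weights.T  # axis 0 of weights is component 1 -> x axis
    lim = np.max(np.abs(w)) or 1.0
    f = w.shape[0]
    if lmap.grid is not None:
        x0, y0 = lmap.grid.anchor
        dx, dy = lmap.grid.delta
        extent = (x0, x0 + dx * f, y0, y0 + dy * f)
    else:
        extent = (0, f, 0, f)

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        w, origin="lower", cmap="RdBu", vmin=-lim, vmax=lim, extent=extent, aspect="auto"
    )
    fig.colorbar(im, ax=ax, label="OPLS-DA weight")
    if contours:
        for hist in contours:
            level = float(np.quantile(hist.values[hist.values > 0], 0.8))
            ax.contour(
                hist.values.T, levels=[level], extent=extent, origin="lower", linewidths=1.0
            )
    if lmap.loadings is not None:
        cx, cy = (extent[0] + extent[1]) / 2, (extent[2] + extent[3]) / 2
        span = min(extent[1] - extent[0], extent[3] - extent[2]) / 2
        norm = np.max(np.linalg.norm(lmap.loadings, axis=1)) or 1.0
        for j, vec in enumerate(lmap.loadings):
            ax.annotate(
                "",
                xy=(cx + vec[0] / norm * span * 0.9, cy + vec[1] / norm * span * 0.9),
                xytext=(cx, cy),
                arrowprops=dict(arrowstyle="->", color="black", lw=1.2),
            )
            name = lmap.marker_names[j] if j < len(lmap.marker_names) else f"m{j + 1}"
            ax.text(
                cx + vec[0] / norm * span * 0.95,
                cy + vec[1] / norm * span * 0.95,
                name,
                fontsize=8,
            )
    ax.set_xlabel("base component (x)")
    ax.set_ylabel("base component (y)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
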