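"""SOM map summaries: per-unit label distributions and feature profiles.

Samples are assigned to units by the prediction-time best matching unit
(plain L2 distance to the prototypes, no neighborhood term), so the maps
drawn here describe exactly what the classifier saw at prediction time.
The numeric tables are the tested surface; the plotting helpers are thin
matplotlib wrappers around them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_INDEX
from .som import SomGrid, SomModel


@dataclass
class MapSummary:
    """Per-unit category counts over the grid.

    ``counts`` maps category name (a label or a decision, e.g. "coding",
    "rejected") to a (rows, cols) integer array; per-unit counts over all
    categories sum to the number of samples mapped to that unit.
    """

    rows: int
    cols: int
    counts: dict[str, np.ndarray]

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def majority(self) -> np.ndarray:
        """(rows, cols) array of majority category names ('' if empty)."""
        names = sorted(self.counts)
        stack = np.stack([self.counts[n] for n in names])
        out = np.array(names, dtype=object)[stack.argmax(axis=0)]
        out[stack.sum(axis=0) == 0] = ""
        return out

    def table(self) -> pd.DataFrame:
        """Long-format table: one row per unit, count column per category."""
        rows = []
        for r in range(self.rows):
            for c in range(self.cols):
                row = {"row": r, "col": c}
                for name in sorted(self.counts):
                    row[f"count_{name}"] = int(self.counts[name][r, c])
                rows.append(row)
        return pd.DataFrame(rows)


def map_label_distribution(
    bmus: np.ndarray, categories: Sequence[str], grid: SomGrid
) -> MapSummary:
    """Aggregate per-unit counts of labels or decisions over the grid.

    ``bmus`` is an (n, 2) array of grid coordinates as returned by
    :func:`somcoding.som.predict`; ``categories`` gives each sample's
    true label or decision.
    """
    bmus = np.atleast_2d(np.asarray(bmus, dtype=int))
    if len(bmus) != len(categories):
        raise ValueError("bmus and categories must have equal length")
    counts: dict[str, np.ndarray] = {}
    for (r, c), cat in zip(bmus, categories):
        if not (0 <= r < grid.rows and 0 <= c < grid.cols):
            raise ValueError(f"BMU ({r}, {c}) outside the {grid.rows}x{grid.cols} grid")
        counts.setdefault(str(cat), np.zeros((grid.rows, grid.cols), dtype=int))[
            r, c
        ] += 1
    return MapSummary(rows=grid.rows, cols=grid.cols, counts=counts)


def feature_profiles(grid: SomGrid, feature_names: Sequence[str]) -> pd.DataFrame:
    """Prototype values of named features, one row per grid unit.

    The values are read straight from the stored prototype vectors, so a
    unit's profile is exactly its representative in feature space.
    """
    idx = []
    for name in feature_names:
        if name not in FEATURE_INDEX:
            raise KeyError(f"unknown feature name {name!r}")
        idx.append(FEATURE_INDEX[name])
    coords = grid.coordinates()
    data = {"row": coords[:, 0], "col": coords[:, 1]}
    for name, j in zip(feature_names, idx):
        data[name] = grid.weights[:, j]
    return pd.DataFrame(data)


def unit_label_entropy(summary: MapSummary, categories: Optional[list[str]] = None) -> np.ndarray:
    """Shannon entropy (nats) of the category mixture at each unit.

    Units with no samples get entropy 0.  Restricting ``categories``
    (e.g. to the two true classes) measures class mixing only.
    """
    names = categories if categories is not None else sorted(summary.counts)
    stack = np.stack(
        [summary.counts.get(n, np.zeros((summary.rows, summary.cols))) for n in names]
    ).astype(float)
    tot = stack.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, stack / np.maximum(tot, 1), 0.0)
        h = np.where(p > 0, -p * np.log(p), 0.0).sum(axis=0)
    return h


# -- plotting (side-effect only; tables above are the tested surface) ----


def plot_label_distribution(summary: MapSummary, path, title: str = "") -> None:
    """Heatmap per category of the per-unit counts; PNG/SVG by suffix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = sorted(summary.counts)
    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.6), squeeze=False)
    for ax, name in zip(axes[0], names):
        im = ax.imshow(summary.counts[name], cmap="viridis", origin="upper")
        ax.set_title(name)
        ax.set_xlabel("col")
        ax.set_ylabel("row")
        fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_feature_profiles(
    model: SomModel, feature_names: Sequence[str], path, title: str = ""
) -> None:
    """Small-multiples heatmaps of prototype feature values over the grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = feature_profiles(model.grid, feature_names)
    n = len(feature_names)
    ncols = min(n, 3)
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3.6 * nrows), squeeze=False)
    for k, name in enumerate(feature_names):
        ax = axes[k // ncols][k % ncols]
        vals = table[name].to_numpy().reshape(model.grid.rows, model.grid.cols)
        im = ax.imshow(vals, cmap="magma", origin="upper")
        ax.set_title(name)
        fig.colorbar(im, ax=ax, shrink=0.8)
    for k in range(n, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
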