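"""Hierarchical clustering and heatmap export of expression profiles.

Profiles are typically per-feature log2 fold-change vectors across RNAi and
untreated conditions. Defaults are euclidean distance with average linkage;
the heatmap uses a diverging green-magenta scale centered at 0 (magenta
high, green low). The numeric artifact is the dendrogram-ordered TSV; the
image is for reporting only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = ["profile_distance", "hclust", "Dendrogram", "heatmap_export"]

_LINKAGES = ("average", "complete", "ward")


def profile_distance(profiles: pd.DataFrame, metric: str = "euclidean") -> pd.DataFrame:
    """Symmetric distance matrix between profile rows.

    ``correlation`` distance is 1 - Pearson r and rejects constant profiles
    (undefined correlation).
    """
    values = profiles.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("profiles contain missing/non-finite values")
    if metric == "correlation":
        if (values.std(axis=1) == 0).any():
            bad = profiles.index[values.std(axis=1) == 0].tolist()[:5]
            raise ValueError(f"constant profile(s) under correlation metric: {bad}")
        condensed = pdist(values, metric="correlation")
    elif metric == "euclidean":
        condensed = pdist(values, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(squareform(condensed), index=profiles.index, columns=profiles.index)


@dataclass
class Dendrogram:
    """Agglomerative merge tree: scipy linkage matrix plus ordered leaves."""

    merges: np.ndarray  # scipy Z, shape (n-1, 4)
    ids: list
    leaf_order: list

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def hclust(dist: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix."""
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    if dist.shape[0] < 2:
        raise ValueError("need at least 2 items")
    mat = dist.to_numpy(dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("non-finite distances")
    if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    z = hierarchy.linkage(squareform(mat, checks=False), method=linkage)
    ids = list(dist.index)
    order = [ids[i] for i in hierarchy.leaves_list(z)]
    return Dendrogram(merges=z, ids=ids, leaf_order=order)


def heatmap_export(
    matrix: pd.DataFrame,
    row_dendrogram: Dendrogram | None,
    col_dendrogram: Dendrogram | None,
    image_path=None,
    tsv_path=None,
) -> pd.DataFrame:
    """Reorder a matrix by dendrogram leaf orders; write TSV and/or image.

    Returns the ordered matrix. Dendrogram leaves must match the matrix ids
    exactly on their axis.
    """
    ordered = matrix
    if row_dendrogram is not None:
        if set(row_dendrogram.leaf_order) != set(matrix.index):
            raise ValueError("row dendrogram leaves do not match matrix rows")
        ordered = ordered.loc[row_dendrogram.leaf_order]
    if col_dendrogram is not None:
        if set(col_dendrogram.leaf_order) != set(matrix.columns):
            raise ValueError("column dendrogram leaves do not match matrix columns")
        ordered = ordered.loc[:, col_dendrogram.leaf_order]
    if tsv_path is not None:
        ordered.to_csv(tsv_path, sep="\t")
    if image_path is not None:
        _render_heatmap(ordered, image_path)
    return ordered


def _render_heatmap(ordered: pd.DataFrame, path) -> None:
    # Agg canvas directly: no interactive backend needed.
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    values = ordered.to_numpy(dtype=float)
    vmax = max(np.abs(values).max(), 1e-12)
    fig = Figure(figsize=(6, 8))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    # PiYG: green at the low end, magenta/pink at the high end
    im = ax.imshow(values, aspect="auto", cmap="PiYG_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(ordered.columns)))
    ax.set_xticklabels(ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2 fold change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
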