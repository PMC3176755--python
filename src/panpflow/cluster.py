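"""Hierarchical agglomerative clustering (complete linkage), row scaling
and heatmap export.

The linkage is complete (maximum inter-cluster distance) with a
deterministic tie-break: among equally close pairs, the one with the
lexicographically smallest (min leaf index, max... ) — concretely the pair
of clusters whose sorted leaf-index tuples compare smallest — is merged.
Complete linkage is inversion-free, so merge heights are non-decreasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "pairwise_distance",
    "hclust_complete",
    "row_scale",
    "render_heatmap",
    "nearest_neighbor_consistency",
]


def nearest_neighbor_consistency(
    matrix: np.ndarray, group_of: list[str], metric: str = "manhattan"
) -> float:
    """Fraction of columns whose nearest other column shares its group label.

    The replicate-clustering sanity check: when every array's nearest
    neighbour is a replicate of the same tissue, replicates pair up
    mutually at the group level.
    """
    d = pairwise_distance(matrix, axis="columns", metric=metric)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=0)
    return float(np.mean([group_of[nn[i]] == group_of[i] for i in range(len(nn))]))


@dataclass
class Dendrogram:
    """Merge list of (node_i, node_j, height); leaves are 0..n−1, the k-th
    merge creates node n+k. ``leaf_order`` is the left-to-right display
    order (at each merge the subtree containing the smaller minimum leaf
    index goes left)."""

    merges: list[tuple[int, int, float]]
    leaf_order: list[int]
    labels: list[str]
    linkage: str = "complete"
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != max(n - 1, 0):
            raise ValueError("a dendrogram over n leaves has n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValueError("complete-linkage heights must be non-decreasing")

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]


def pairwise_distance(
    matrix: np.ndarray, axis: str = "rows", metric: str = "euclidean"
) -> np.ndarray:
    """Symmetric zero-diagonal distance matrix over rows or columns."""
    m = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("distance input must be finite (no NaN)")
    if axis == "columns":
        m = m.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if m.shape[0] < 2:
        raise ValueError("need at least two items")
    if metric == "manhattan":
        metric = "cityblock"
    elif metric != "euclidean":
        raise ValueError(f"unsupported metric {metric!r}")
    return squareform(pdist(m, metric=metric))


def hclust_complete(
    dist: np.ndarray, labels: list[str] | None = None, metric: str = "euclidean"
) -> Dendrogram:
    """Agglomerative clustering with complete linkage.

    Naive O(n³) scheme, adequate for array-scale inputs; deterministic
    under distance ties (smallest sorted-leaf-tuple pair merges first).
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
        raise ValueError("expected a symmetric zero-diagonal distance matrix")
    if labels is None:
        labels = [str(i) for i in range(n)]

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}  # node -> leaves
    active = list(range(n))
    cd = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float]] = []
    order: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_node = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                h = cd[key]
                tiebreak = (h, tuple(sorted(clusters[i] + clusters[j])))
                if best is None or tiebreak < best[0]:
                    best = (tiebreak, i, j)
        (_h, _), i, j = best
        height = cd[(min(i, j), max(i, j))]
        merges.append((min(i, j), max(i, j), height))
        new = next_node
        next_node += 1
        clusters[new] = sorted(clusters[i] + clusters[j])
        left, right = order[i], order[j]
        if min(right) < min(left):
            left, right = right, left
        order[new] = left + right
        active = [a for a in active if a not in (i, j)]
        for a in active:
            cd[(min(a, new), max(a, new))] = max(
                cd[(min(a, i), max(a, i))], cd[(min(a, j), max(a, j))]
            )
        active.append(new)

    leaf_order = order[active[0]] if active else []
    return Dendrogram(
        merges=merges, leaf_order=leaf_order, labels=labels, metric=metric
    )


def row_scale(matrix: np.ndarray) -> np.ndarray:
    """Center each row and divide by its population SD (divisor n).

    Constant rows map to all-zero with a warning; display convention only.
    """
    m = np.asarray(matrix, dtype=float)
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{constant.sum()} constant row(s) scaled to zero")
    out = np.where(sd > 0, (m - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def render_heatmap(
    matrix: np.ndarray,
    row_labels: list[str],
    col_labels: list[str],
    path,
    row_dendrogram: Dendrogram | None = None,
    col_dendrogram: Dendrogram | None = None,
    scale_rows: bool = True,
):
    """Write a raster heatmap and the reordered scaled matrix as TSV.

    The TSV (``<path>.tsv``) is the testable artifact: rows/columns follow
    the dendrogram leaf orders. Returns the ordered DataFrame.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = np.asarray(matrix, dtype=float)
    if row_dendrogram is not None:
        if row_dendrogram.labels != list(row_labels):
            raise ValueError("row dendrogram labels do not match matrix rows")
        ridx = row_dendrogram.leaf_order
    else:
        ridx = list(range(m.shape[0]))
    if col_dendrogram is not None:
        if col_dendrogram.labels != list(col_labels):
            raise ValueError("column dendrogram labels do not match matrix columns")
        cidx = col_dendrogram.leaf_order
    else:
        cidx = list(range(m.shape[1]))

    display = row_scale(m) if scale_rows else m
    display = display[np.ix_(ridx, cidx)]
    df = pd.DataFrame(
        display,
        index=[row_labels[i] for i in ridx],
        columns=[col_labels[j] for j in cidx],
    )
    df.to_csv(f"{path}.tsv", sep="\t", index_label="row_id")

    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * len(cidx)), max(3, 0.12 * len(ridx)))
    )
    im = ax.imshow(display, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(cidx)))
    ax.set_xticklabels(df.columns, rotation=90, fontsize=5)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return df
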