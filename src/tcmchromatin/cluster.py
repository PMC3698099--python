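"""Agglomerative hierarchical clustering of entity x attribute matrices.

Entities (medicinals or formulas) are 18-attribute potency arrays compared
by Euclidean distance; the two closest clusters are merged repeatedly
(complete linkage by default).  Ties at equal merge distance are broken by
the smallest cluster index (leaves 0..n-1 in input order, then merge
creation order), which makes trees bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import ATTRIBUTE_ORDER
from .profiling import PotencyProfile

LINKAGES = ("complete", "average", "single")


def potency_matrix(profiles: list[PotencyProfile],
                   mode: str = "count") -> pd.DataFrame:
    """Entities x 18 matrix, rows in input order, columns in catalog order."""
    if not profiles:
        raise ValueError("no profiles supplied")
    data = np.array([p.potency(mode) for p in profiles])
    return pd.DataFrame(data, index=[p.entity_id for p in profiles],
                        columns=list(ATTRIBUTE_ORDER))


@dataclass
class Dendrogram:
    """Binary merge tree; cluster ids follow the scipy convention.

    Leaves are 0..n-1; merge k creates cluster n+k.  ``merges[k]`` is
    (cluster_a, cluster_b, height) with a < b.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + k: (a, b) for k, (a, b, _) in enumerate(self.merges)}

    def leaf_order(self) -> list[int]:
        """Leaf indices by recursive left-to-right traversal."""
        if not self.merges:
            return [0]
        children = self._children()
        order: list[int] = []
        stack = [self.n_leaves + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node in children:
                a, b = children[node]
                stack.append(b)
                stack.append(a)
            else:
                order.append(node)
        return order

    def to_newick(self) -> str:
        """Newick with branch length = parent height - child height."""
        children = self._children()
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        for k, (_, _, h) in enumerate(self.merges):
            height[n + k] = h

        def render(node: int, parent_h: float) -> str:
            blen = parent_h - height[node]
            if node in children:
                a, b = children[node]
                inner = f"({render(a, height[node])},{render(b, height[node])})"
                return f"{inner}:{blen:g}"
            return f"{self.labels[node]}:{blen:g}"

        root = n + len(self.merges) - 1 if self.merges else 0
        if not self.merges:
            return f"{self.labels[0]};"
        a, b = children[root]
        h = height[root]
        return f"({render(a, h)},{render(b, h)});"


def hierarchical_cluster(matrix, axis: str = "rows",
                         linkage: str = "complete",
                         z_score: bool = False) -> Dendrogram:
    """Cluster rows or columns of a matrix under Euclidean distance.

    ``z_score`` optionally standardizes each feature (off by default; the
    potency matrices are clustered unscaled).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    if axis not in ("rows", "columns"):
        raise ValueError(f"unknown axis {axis!r}")
    if isinstance(matrix, pd.DataFrame):
        data = matrix.to_numpy(dtype=float)
        labels = list(matrix.index if axis == "rows" else matrix.columns)
    else:
        data = np.asarray(matrix, dtype=float)
        labels = None
    if axis == "columns":
        data = data.T
    if labels is None:
        labels = [str(i) for i in range(len(data))]
    n = len(data)
    if n < 2:
        raise ValueError("clustering needs at least 2 items")
    if z_score:
        sd = data.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        data = (data - data.mean(axis=0)) / sd

    total = 2 * n - 1
    D = np.full((total, total), np.inf)
    diff = data[:, None, :] - data[None, :, :]
    D[:n, :n] = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(D, np.inf)
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        m = n + step
        sub = D[:m, :m].copy()
        sub[~active[:m], :] = np.inf
        sub[:, ~active[:m]] = np.inf
        sub[np.tril_indices(m)] = np.inf
        flat = int(np.argmin(sub))
        i, j = divmod(flat, m)
        h = float(sub[i, j])
        # Lance-Williams update for the new cluster
        di, dj = D[i, :m], D[j, :m]
        if linkage == "complete":
            dnew = np.maximum(di, dj)
        elif linkage == "single":
            dnew = np.minimum(di, dj)
        else:  # average
            dnew = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
        D[m, :m] = dnew
        D[:m, m] = dnew
        D[m, m] = np.inf
        active[i] = active[j] = False
        active[m] = True
        sizes[m] = sizes[i] + sizes[j]
        merges.append((i, j, h))
    return Dendrogram(labels=labels, merges=merges)


def export_clustered_matrix(matrix: pd.DataFrame,
                            row_dendro: Dendrogram | None,
                            col_dendro: Dendrogram | None,
                            path_prefix: str,
                            image: bool = False) -> dict[str, str]:
    """Write the reordered matrix, the dendrograms and optionally a heatmap.

    Returns the paths written, keyed by artifact kind.
    """
    out: dict[str, str] = {}
    rows = list(matrix.index)
    cols = list(matrix.columns)
    if row_dendro is not None:
        if row_dendro.labels != rows:
            raise ValueError("row dendrogram does not match matrix rows")
        rows = [row_dendro.labels[i] for i in row_dendro.leaf_order()]
    if col_dendro is not None:
        if col_dendro.labels != cols:
            raise ValueError("column dendrogram does not match matrix columns")
        cols = [col_dendro.labels[i] for i in col_dendro.leaf_order()]
    ordered = matrix.loc[rows, cols]
    matrix_path = f"{path_prefix}_matrix.tsv"
    ordered.to_csv(matrix_path, sep="\t")
    out["matrix"] = matrix_path
    if row_dendro is not None:
        p = f"{path_prefix}_rows.nwk"
        with open(p, "w") as fh:
            fh.write(row_dendro.to_newick() + "\n")
        out["row_dendrogram"] = p
    if col_dendro is not None:
        p = f"{path_prefix}_cols.nwk"
        with open(p, "w") as fh:
            fh.write(col_dendro.to_newick() + "\n")
        out["col_dendrogram"] = p
    if image:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, max(3, 0.12 * len(rows))))
        im = ax.imshow(ordered.to_numpy(dtype=float), aspect="auto",
                       cmap="viridis")
        ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=6)
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, label="potency")
        p = f"{path_prefix}_heatmap.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        out["heatmap"] = p
    return out
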