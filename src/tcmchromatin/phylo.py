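"""Phylogenetic autocorrelation of TCM scores via Moran's I.

The statistic is

    I = (n / S0) * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2

with S0 the sum of the weights and w_ij = 1 / d_ij, the reciprocal of the
cophenetic (path-length) distance between leaves i and j.  The null
expectation is E[I] = -1/(n-1).  Significance is available analytically
(normal approximation with the randomization-assumption variance) or by
label permutation.

Weights are used raw by default; ``row_standardize=True`` divides each row
by its sum, which reproduces the convention of ape's Moran.I.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

from .catalog import CatalogError, MedicinalCatalog


@dataclass
class MoranResult:
    I: float
    expected_I: float
    n: int
    method: str  # "statistic", "analytic" or "permutation"
    variance_I: float | None = None
    p_value: float | None = None
    z: float | None = None
    n_permutations: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "I": self.I, "expected_I": self.expected_I, "n": self.n,
            "method": self.method, "variance_I": self.variance_I,
            "p_value": self.p_value, "z": self.z,
            "n_permutations": self.n_permutations, "seed": self.seed,
        }


def cophenetic_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """All-pairs path-length distances between leaves.

    Returns the leaf labels (tree traversal order) and the symmetric
    distance matrix.  Computed by a single postorder sweep: at each
    internal node the distances between leaves of distinct child subtrees
    are their root-ward path lengths through that node.
    """
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise CatalogError("cophenetic distances require at least 2 leaves")
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))
    # node -> {leaf index: distance from node to leaf}
    below: dict[int, dict[int, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = {index[id(node)]: 0.0}
            continue
        merged: dict[int, float] = {}
        for child in node.child_nodes():
            sub = below.pop(id(child))
            elen = child.edge.length if child.edge.length is not None else 1.0
            sub = {i: d + elen for i, d in sub.items()}
            for i, di in sub.items():
                for j, dj in merged.items():
                    D[i, j] = D[j, i] = di + dj
            merged.update(sub)
        below[id(node)] = merged
    return labels, D


def inverse_distance_weights(D: np.ndarray) -> np.ndarray:
    """w_ij = 1/d_ij off-diagonal, zero diagonal."""
    D = np.asarray(D, dtype=float)
    off = ~np.eye(len(D), dtype=bool)
    if np.any(D[off] == 0):
        raise CatalogError(
            "zero off-diagonal cophenetic distance: duplicate taxa present; "
            "deduplicate the catalog before computing weights")
    W = np.zeros_like(D)
    W[off] = 1.0 / D[off]
    return W


def _drop_na(y: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = ~np.isnan(y)
    return y[keep], W[np.ix_(keep, keep)]


def _statistic(y: np.ndarray, W: np.ndarray) -> float:
    n = len(y)
    z = y - y.mean()
    s0 = W.sum()
    return (n / s0) * (z @ W @ z) / (z @ z)


def _validate(y: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.shape != (len(y), len(y)):
        raise ValueError("weight matrix shape does not match trait length")
    y, W = _drop_na(y, W)
    if len(y) < 3:
        raise CatalogError(f"Moran's I needs >= 3 non-NA observations, got {len(y)}")
    if np.ptp(y) == 0:
        raise CatalogError("constant trait: Moran's I denominator is zero")
    return y, W


def morans_i(y: np.ndarray, W: np.ndarray,
             row_standardize: bool = False) -> MoranResult:
    """Moran's I statistic only (no significance).

    NA trait entries are removed together with their weight rows/columns.
    """
    y, W = _validate(y, W)
    if row_standardize:
        W = _row_standardize(W)
    n = len(y)
    return MoranResult(I=_statistic(y, W), expected_I=-1.0 / (n - 1), n=n,
                       method="statistic")


def _row_standardize(W: np.ndarray) -> np.ndarray:
    rowsum = W.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return W / rowsum


def _randomization_variance(z: np.ndarray, W: np.ndarray) -> float:
    n = len(z)
    s0 = W.sum()
    s1 = 0.5 * ((W + W.T) ** 2).sum()
    s2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    b2 = n * (z ** 4).sum() / (z ** 2).sum() ** 2
    num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
    den = (n - 1) * (n - 2) * (n - 3) * s0 * s0
    return num / den - 1.0 / (n - 1) ** 2


def morans_i_significance(y: np.ndarray, W: np.ndarray, method: str = "analytic",
                          n_permutations: int = 999, seed: int | None = None,
                          row_standardize: bool = False) -> MoranResult:
    """Moran's I with a two-sided P-value.

    ``analytic`` uses the normal approximation with the randomization
    (permutation-moment) variance; ``permutation`` shuffles trait labels
    and reports (1 + #{|I* - E| >= |I - E|}) / (1 + n_permutations).
    """
    y, W = _validate(y, W)
    if row_standardize:
        W = _row_standardize(W)
    n = len(y)
    expected = -1.0 / (n - 1)
    obs = _statistic(y, W)
    if method == "analytic":
        z = y - y.mean()
        var = _randomization_variance(z, W)
        zscore = (obs - expected) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(zscore))
        return MoranResult(I=obs, expected_I=expected, n=n, method="analytic",
                           variance_I=var, p_value=max(p, np.nextafter(0, 1)),
                           z=zscore)
    if method == "permutation":
        if n_permutations < 99:
            raise ValueError("permutation test needs n_permutations >= 99")
        rng = np.random.default_rng(seed)
        z = y - y.mean()
        s0 = W.sum()
        zz = z @ z
        ref = abs(obs - expected)
        hits = 0
        perms = np.empty(n_permutations)
        for k in range(n_permutations):
            zp = rng.permutation(z)
            perms[k] = (n / s0) * (zp @ W @ zp) / zz
        hits = int(np.sum(np.abs(perms - expected) >= ref - 1e-12))
        p = (1 + hits) / (1 + n_permutations)
        return MoranResult(I=obs, expected_I=expected, n=n, method="permutation",
                           variance_I=float(perms.var(ddof=0)), p_value=p,
                           n_permutations=n_permutations, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def build_tree_from_lineages(catalog: MedicinalCatalog) -> dendropy.Tree:
    """Build a cladogram from root-to-species lineage strings.

    Internal nodes are shared lineage prefixes; every rank step is one edge
    of length 1, so cophenetic distance counts the edges below the deepest
    shared taxon.  Each medicinal's leaf is the node of its terminal taxon.
    Polytomies are allowed; a taxon appearing under two different parents,
    a duplicated full lineage, or a terminal taxon that is also internal
    all raise.
    """
    records = [rec for rec in catalog]
    if any(not rec.lineage for rec in records):
        bad = [r.medicinal_id for r in records if not r.lineage][:5]
        raise CatalogError(f"records without lineage: {bad}")
    if len(records) < 2:
        raise CatalogError("lineage tree needs at least 2 medicinals")
    taxon_parent: dict[str, tuple[str, ...]] = {}
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    node_at: dict[tuple[str, ...], dendropy.Node] = {(): tree.seed_node}
    for rec in records:
        prefix: tuple[str, ...] = ()
        for taxon in rec.lineage:
            parent = prefix
            prefix = prefix + (taxon,)
            if taxon in taxon_parent and taxon_parent[taxon] != parent:
                raise CatalogError(
                    f"inconsistent lineages: taxon {taxon!r} appears under "
                    f"{taxon_parent[taxon]!r} and {parent!r}")
            taxon_parent[taxon] = parent
            if prefix not in node_at:
                child = dendropy.Node()
                child.edge.length = 1.0
                node_at[parent].add_child(child)
                node_at[prefix] = child
        leaf = node_at[prefix]
        if leaf.taxon is not None:
            raise CatalogError(
                f"medicinals {leaf.taxon.label!r} and {rec.medicinal_id!r} "
                f"share the full lineage {rec.lineage!r}; disambiguate them")
        leaf.taxon = tns.new_taxon(rec.medicinal_id)
    for node in tree.preorder_node_iter():
        if node.taxon is not None and node.child_nodes():
            raise CatalogError(
                f"lineage of {node.taxon.label!r} terminates at a taxon that "
                f"is internal to another lineage; disambiguate it")
    return tree


def morans_i_for_tree(tree: dendropy.Tree, scores, method: str = "analytic",
                      n_permutations: int = 999, seed: int | None = None,
                      row_standardize: bool = False) -> MoranResult:
    """Align a medicinal_id -> score mapping with the tree and test it."""
    labels, D = cophenetic_distances(tree)
    W = inverse_distance_weights(D)
    y = np.array([float(scores.get(lab, np.nan)) for lab in labels])
    return morans_i_significance(y, W, method=method,
                                 n_permutations=n_permutations, seed=seed,
                                 row_standardize=row_standardize)
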