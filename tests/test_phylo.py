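import itertools
import subprocess

import dendropy
import numpy as np
import pytest

from tcmchromatin.catalog import (
    CatalogError,
    MedicinalCatalog,
    MedicinalRecord,
    read_tree,
)
from tcmchromatin.phylo import (
    build_tree_from_lineages,
    cophenetic_distances,
    inverse_distance_weights,
    morans_i,
    morans_i_for_tree,
    morans_i_significance,
)
from .conftest import random_weight_matrix


def brute_force_moran(y, W):
    """Independent double-loop evaluation of the Moran's I formula."""
    n = len(y)
    ybar = sum(y) / n
    s0 = sum(W[i][j] for i in range(n) for j in range(n))
    num = sum(W[i][j] * (y[i] - ybar) * (y[j] - ybar)
              for i in range(n) for j in range(n))
    den = sum((yi - ybar) ** 2 for yi in y)
    return (n / s0) * num / den


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


class TestCopheneticDistances:
    def test_cherry(self):
        labels, D = cophenetic_distances(_tree("(A:1,B:1);"))
        assert D[labels.index("A"), labels.index("B")] == 2.0
        assert np.all(np.diag(D) == 0)

    def test_balanced_four_leaf(self):
        labels, D = cophenetic_distances(
            _tree("((A:1,B:1):1,(C:1,D:1):1);"))
        idx = {lab: i for i, lab in enumerate(labels)}
        assert D[idx["A"], idx["B"]] == 2.0
        assert D[idx["C"], idx["D"]] == 2.0
        assert D[idx["A"], idx["C"]] == 4.0
        assert np.allclose(D, D.T)

    def test_matches_dendropy_phylogenetic_distance_matrix(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(4, 9))
            taxa = [f"T{i}" for i in range(n)]
            tree = self._random_tree(rng, taxa)
            labels, D = cophenetic_distances(tree)
            pdm = tree.phylogenetic_distance_matrix()
            taxon = {t.label: t for t in tree.taxon_namespace}
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    if i < j:
                        assert D[i, j] == pytest.approx(
                            pdm.patristic_distance(taxon[a], taxon[b]))

    @staticmethod
    def _random_tree(rng, taxa):
        tns = dendropy.TaxonNamespace()
        nodes = []
        for lab in taxa:
            node = dendropy.Node()
            node.taxon = tns.new_taxon(lab)
            node.edge.length = float(rng.random() + 0.1)
            nodes.append(node)
        while len(nodes) > 2:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            parent = dendropy.Node()
            parent.edge.length = float(rng.random() + 0.1)
            parent.add_child(nodes[i])
            parent.add_child(nodes[j])
            nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
            nodes.append(parent)
        tree = dendropy.Tree(taxon_namespace=tns)
        for node in nodes:
            tree.seed_node.add_child(node)
        return tree

    def test_single_leaf_errors(self):
        with pytest.raises(CatalogError):
            cophenetic_distances(_tree("(A:1);"))


class TestInverseDistanceWeights:
    def test_reciprocal_and_zero_diagonal(self):
        labels, D = cophenetic_distances(
            _tree("((A:1,B:1):1,(C:1,D:1):1);"))
        W = inverse_distance_weights(D)
        assert np.all(np.diag(W) == 0)
        off = ~np.eye(4, dtype=bool)
        assert set(np.round(W[off], 10)) == {0.5, 0.25}

    def test_zero_off_diagonal_distance_errors_mentioning_dedup(self):
        D = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(CatalogError, match="[Dd]edup"):
            inverse_distance_weights(D)


class TestMoransI:
    def test_uniform_weights_give_null_expectation(self):
        """With equal off-diagonal weights I collapses to -1/(n-1)."""
        n = 4
        W = np.ones((n, n)) - np.eye(n)
        res = morans_i(np.array([1.0, 2.0, 5.0, -1.0]), W)
        assert res.I == pytest.approx(-1 / 3, abs=1e-12)
        assert res.expected_I == pytest.approx(-1 / 3)

    def test_constant_trait_errors(self):
        W = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(CatalogError, match="constant"):
            morans_i(np.full(4, 2.0), W)

    def test_too_few_observations_error(self):
        W = np.ones((2, 2)) - np.eye(2)
        with pytest.raises(CatalogError, match=">= 3"):
            morans_i(np.array([1.0, 2.0]), W)

    def test_na_rows_dropped_in_tandem_with_weights(self):
        rng = np.random.default_rng(3)
        W = random_weight_matrix(rng, 6)
        y = rng.normal(size=6)
        y_na = y.copy()
        y_na[2] = np.nan
        keep = [0, 1, 3, 4, 5]
        direct = morans_i(y[keep], W[np.ix_(keep, keep)])
        via_na = morans_i(y_na, W)
        assert via_na.I == pytest.approx(direct.I)
        assert via_na.n == 5

    def test_matches_brute_force_on_random_tree_instances(self):
        """Statistic equals an independent O(n^2) double-loop to 1e-12."""
        rng = np.random.default_rng(11)
        for rep in range(20):
            n = int(rng.integers(6, 11))
            tree = TestCopheneticDistances._random_tree(
                rng, [f"T{i}" for i in range(n)])
            _, D = cophenetic_distances(tree)
            W = inverse_distance_weights(D)
            y = rng.normal(size=n)
            assert morans_i(y, W).I == pytest.approx(
                brute_force_moran(list(y), W.tolist()), abs=1e-12)

    def test_clustered_trait_is_positive(self):
        tree = _tree("(((A:1,B:1):1,C:2):1,((D:1,E:1):1,F:2):1);")
        labels, D = cophenetic_distances(tree)
        W = inverse_distance_weights(D)
        y = np.array([1.0 if lab in "ABC" else -1.0 for lab in labels])
        y += np.linspace(0, 0.1, 6)  # break exact symmetry
        assert morans_i(y, W).I > 0

    def test_scale_shift_invariance(self):
        rng = np.random.default_rng(5)
        W = random_weight_matrix(rng, 8)
        y = rng.normal(size=8)
        base = morans_i(y, W).I
        assert morans_i(3.5 * y - 2.0, W).I == pytest.approx(base)
        assert morans_i(-y, W).I == pytest.approx(base)

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(6)
        W = random_weight_matrix(rng, 8)
        y = rng.normal(size=8)
        assert morans_i(y, 7.0 * W).I == pytest.approx(morans_i(y, W).I)


class TestSignificance:
    def test_expected_value_reported_in_both_methods(self):
        rng = np.random.default_rng(8)
        W = random_weight_matrix(rng, 10)
        y = rng.normal(size=10)
        for method in ("analytic", "permutation"):
            res = morans_i_significance(y, W, method=method, seed=1)
            assert res.expected_I == pytest.approx(-1 / 9)
            assert 0 < res.p_value <= 1

    def test_too_few_permutations_error(self):
        rng = np.random.default_rng(9)
        W = random_weight_matrix(rng, 6)
        with pytest.raises(ValueError, match="99"):
            morans_i_significance(rng.normal(size=6), W,
                                  method="permutation", n_permutations=10)

    def test_exhaustive_permutation_tail_mass_six_leaves(self):
        """MC permutation p agrees with the exact 720-relabeling tail mass."""
        rng = np.random.default_rng(10)
        tree = TestCopheneticDistances._random_tree(
            rng, [f"T{i}" for i in range(6)])
        _, D = cophenetic_distances(tree)
        W = inverse_distance_weights(D)
        y = np.array([1.0, 1.2, 0.9, -1.0, -1.1, -0.8])
        n = 6
        z = y - y.mean()
        s0, zz = W.sum(), (y - y.mean()) @ (y - y.mean())
        E = -1 / (n - 1)
        obs = morans_i(y, W).I
        tail = sum(
            abs((n / s0) * (z[list(p)] @ W @ z[list(p)]) / zz - E)
            >= abs(obs - E) - 1e-12
            for p in itertools.permutations(range(n)))
        exact = tail / 720
        res = morans_i_significance(y, W, method="permutation",
                                    n_permutations=4999, seed=0)
        se = np.sqrt(exact * (1 - exact) / 4999)
        assert abs(res.p_value - exact) < 3 * se + 1e-3

    def test_permutation_null_mean_is_expected_i(self):
        """Mean of I over shuffles converges to -1/(n-1) (n=30, 10k perms)."""
        rng = np.random.default_rng(12)
        n = 30
        W = random_weight_matrix(rng, n)
        y = rng.normal(size=n)
        z = y - y.mean()
        s0, zz = W.sum(), z @ z
        vals = np.empty(10_000)
        for k in range(len(vals)):
            zp = rng.permutation(z)
            vals[k] = (n / s0) * (zp @ W @ zp) / zz
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - (-1 / (n - 1))) < 3 * se

    def test_analytic_variance_matches_permutation_variance(self):
        rng = np.random.default_rng(13)
        n = 20
        W = random_weight_matrix(rng, n)
        y = rng.normal(size=n)
        analytic = morans_i_significance(y, W, method="analytic")
        perm = morans_i_significance(y, W, method="permutation",
                                     n_permutations=20_000, seed=2)
        # permutation variance of I has MC error ~ var * sqrt(2/nperm)
        assert perm.variance_I == pytest.approx(
            analytic.variance_I, rel=0.1)

    def test_matches_r_ape_moran_i(self, tmp_path):
        """Row-standardized mode reproduces ape::Moran.I exactly."""
        rng = np.random.default_rng(42)
        n = 10
        W = random_weight_matrix(rng, n)
        y = rng.normal(size=n)
        np.savetxt(tmp_path / "w.txt", W)
        np.savetxt(tmp_path / "y.txt", y)
        script = (
            'suppressMessages(library(ape));'
            f'W <- as.matrix(read.table("{tmp_path}/w.txt"));'
            f'y <- scan("{tmp_path}/y.txt", quiet=TRUE);'
            'r <- Moran.I(y, W);'
            'cat(sprintf("%.12f %.12f %.12f %.12f", r$observed, r$expected,'
            ' r$sd, r$p.value))')
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        obs, exp, sd, p = map(float, out.stdout.split())
        res = morans_i_significance(y, W, method="analytic",
                                    row_standardize=True)
        assert res.I == pytest.approx(obs, abs=1e-10)
        assert res.expected_I == pytest.approx(exp, abs=1e-10)
        assert np.sqrt(res.variance_I) == pytest.approx(sd, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)


class TestLineageTree:
    @staticmethod
    def _catalog(lineages):
        recs = [MedicinalRecord(f"M{i}", lineage=tuple(lin))
                for i, lin in enumerate(lineages)]
        return MedicinalCatalog({r.medicinal_id: r for r in recs})

    def test_shared_genus_distance_two(self):
        cat = self._catalog([("Plantae", "Rosa", "sp1"),
                             ("Plantae", "Rosa", "sp2")])
        tree = build_tree_from_lineages(cat)
        labels, D = cophenetic_distances(tree)
        assert D[0, 1] == 2.0

    def test_same_order_different_families_distance_four(self):
        cat = self._catalog([
            ("Rosales", "Rosaceae", "Rosa", "sp1"),
            ("Rosales", "Moraceae", "Morus", "sp2"),
        ])
        tree = build_tree_from_lineages(cat)
        _, D = cophenetic_distances(tree)
        assert D[0, 1] == 6.0  # three edges below the shared order each side

    def test_inconsistent_parent_errors(self):
        cat = self._catalog([("A", "X", "sp1"), ("B", "X", "sp2")])
        with pytest.raises(CatalogError, match="inconsistent"):
            build_tree_from_lineages(cat)

    def test_single_record_errors(self):
        cat = self._catalog([("A", "B", "sp1")])
        with pytest.raises(CatalogError, match="at least 2"):
            build_tree_from_lineages(cat)

    def test_duplicate_full_lineage_errors(self):
        cat = self._catalog([("A", "B", "sp1"), ("A", "B", "sp1")])
        with pytest.raises(CatalogError, match="share the full lineage"):
            build_tree_from_lineages(cat)


class TestTreePipelineGlue:
    def test_morans_i_for_tree_drops_unscored_leaves(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(((A:1,B:1):1,C:2):1,((D:1,E:1):1,F:2):1);\n")
        tree = read_tree(p)
        scores = {"A": 1.0, "B": 1.2, "C": 0.8, "D": -1.0, "E": -1.2,
                  "F": float("nan")}
        res = morans_i_for_tree(tree, scores)
        assert res.n == 5
        assert res.I > 0
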