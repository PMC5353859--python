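import itertools
import math

import numpy as np
import pandas as pd
import pytest

from secrepath.clustering import (
    ClusteringError,
    average_linkage_tree,
    au_pvalues,
    bootstrap_support,
    significant_clusters,
    spearman_distance_matrix,
    support_table,
    tree_from_values,
)


def upgma_oracle(dist: pd.DataFrame):
    """Brute-force UPGMA over the original distance matrix.

    Cluster distance is computed from scratch as the mean over all original
    cross pairs (summed in deterministic sorted order); ties within a 1e-9
    tolerance break on the sorted-id rank pair, mirroring the documented
    rule. Returns (frozenset leaf set, height) per merge.
    """
    tol = 1e-9
    labels = list(dist.index)
    rank = {lab: r for r, lab in enumerate(sorted(labels))}
    clusters = [frozenset([lab]) for lab in labels]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            value = math.fsum(
                sorted(dist.loc[x, y] for x in a for y in b)
            ) / (len(a) * len(b))
            key = tuple(sorted((min(rank[x] for x in a), min(rank[x] for x in b))))
            if (
                best is None
                or value < best[0] - tol
                or (value <= best[0] + tol and key < best[1:3])
            ):
                best = (value, key[0], key[1], a, b)
        value, _, _, a, b = best
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
        merges.append((a | b, value))
    return merges


class TestSpearmanDistance:
    def test_self_distance_zero(self, small_expression):
        dist = spearman_distance_matrix(small_expression)
        assert np.allclose(np.diag(dist), 0.0)

    def test_anti_monotone_distance_two(self):
        values = pd.DataFrame(
            {"up": [1.0, 2, 3, 4, 5], "down": [9.0, 7, 5, 3, 1]}
        ).T
        dist = spearman_distance_matrix(values)
        assert dist.loc["up", "down"] == pytest.approx(2.0)

    def test_rank_invariance_under_monotone_transform(self, small_expression):
        dist1 = spearman_distance_matrix(small_expression)
        transformed = small_expression.copy()
        transformed.loc["a0"] = np.exp(transformed.loc["a0"])
        dist2 = spearman_distance_matrix(transformed)
        assert np.allclose(dist1.loc["a0"], dist2.loc["a0"])

    def test_bounds_and_symmetry(self, small_expression):
        dist = spearman_distance_matrix(small_expression)
        arr = dist.to_numpy()
        assert ((arr >= 0) & (arr <= 2)).all()
        assert np.allclose(arr, arr.T)

    def test_constant_gene_excluded_with_warning(self, small_expression):
        values = small_expression.copy()
        values.loc["flat"] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            dist = spearman_distance_matrix(values)
        assert "flat" not in dist.index

    def test_too_few_samples(self):
        with pytest.raises(ClusteringError):
            spearman_distance_matrix(pd.DataFrame({"g": [1.0, 2.0]}).T)

    def test_missing_gene(self, small_expression):
        with pytest.raises(ClusteringError):
            spearman_distance_matrix(small_expression, genes=["nope"])


class TestAverageLinkage:
    def test_hand_upgma(self):
        dist = pd.DataFrame(
            [[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        tree = average_linkage_tree(dist)
        sets = tree.leaf_sets()
        assert sets[0] == frozenset("AB")
        assert tree.heights()[0] == pytest.approx(0.1)
        assert sets[1] == frozenset("ABC")
        assert tree.heights()[1] == pytest.approx(0.9)

    def test_identical_profiles_zero_height(self):
        values = pd.DataFrame(
            {"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8], "z": [5.0, 1, 2, 0]}
        ).T
        tree = tree_from_values(values)
        assert tree.heights()[0] == pytest.approx(0.0)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(13)
        for n in (3, 4, 5):
            for _ in range(40):
                labels = [f"L{i}" for i in range(n)]
                # grid-valued distances exercise tie handling
                raw = rng.integers(1, 6, size=(n, n)).astype(float) / 5.0
                d = (raw + raw.T) / 2
                np.fill_diagonal(d, 0.0)
                dist = pd.DataFrame(d, index=labels, columns=labels)
                tree = average_linkage_tree(dist)
                got = list(zip(tree.leaf_sets(), tree.heights()))
                expected = upgma_oracle(dist)
                for (gs, gh), (es, eh) in zip(got, expected):
                    assert gs == es
                    assert gh == pytest.approx(eh)

    def test_non_symmetric_rejected(self):
        dist = pd.DataFrame(
            [[0.0, 1.0], [2.0, 0.0]], index=list("ab"), columns=list("ab")
        )
        with pytest.raises(ClusteringError, match="symmetric"):
            average_linkage_tree(dist)

    def test_heights_non_decreasing(self, small_expression):
        tree = tree_from_values(small_expression)
        heights = tree.heights()
        assert (np.diff(heights) >= -1e-9).all()

    def test_fast_engine_agrees_on_tie_free_distances(self):
        # engines may differ on exact ties (documented); on tie-free
        # continuous distances the trees must be identical
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        from secrepath.clustering import ClusterTree

        rng = np.random.default_rng(14)
        for _ in range(10):
            n = 20
            labels = [f"g{i}" for i in range(n)]
            raw = rng.uniform(0.1, 2.0, size=(n, n))
            d = (raw + raw.T) / 2
            np.fill_diagonal(d, 0.0)
            dist = pd.DataFrame(d, index=labels, columns=labels)
            exact = average_linkage_tree(dist)
            z = linkage(squareform(d, checks=False), method="average")
            fast = ClusterTree(leaves=labels, merges=z[:, :3])
            assert set(exact.leaf_sets()) == set(fast.leaf_sets())
            assert np.allclose(sorted(exact.heights()), sorted(fast.heights()))


class TestBootstrapSupport:
    def test_planted_modules_high_bp(self, small_expression):
        tree = tree_from_values(small_expression)
        tree = bootstrap_support(small_expression, tree, nboot=200, seed=5)
        sets = tree.leaf_sets()
        module_a = frozenset(f"a{i}" for i in range(4))
        module_b = frozenset(f"b{i}" for i in range(4))
        bp = {sets[k]: tree.bp[k] for k in range(len(sets))}
        assert bp[module_a] >= 0.95
        assert bp[module_b] >= 0.95

    def test_independent_genes_low_bp(self):
        rng = np.random.default_rng(15)
        values = pd.DataFrame(
            rng.standard_normal((12, 20)), index=[f"g{i}" for i in range(12)]
        )
        tree = tree_from_values(values)
        tree = bootstrap_support(values, tree, nboot=100, seed=6)
        # module-sized (>=3 leaves, not root) nodes are unstable on noise
        sizes = np.array([len(s) for s in tree.leaf_sets()])
        inner = (sizes >= 3) & (sizes < 12)
        assert tree.bp[inner].mean() < 0.3

    def test_reproducible_under_seed(self, small_expression):
        t1 = bootstrap_support(small_expression, nboot=50, seed=9)
        t2 = bootstrap_support(small_expression, nboot=50, seed=9)
        assert np.array_equal(t1.bp, t2.bp)

    def test_nboot_zero_error(self, small_expression):
        with pytest.raises(ClusteringError):
            bootstrap_support(small_expression, nboot=0)

    def test_root_always_present(self, small_expression):
        tree = bootstrap_support(small_expression, nboot=50, seed=1)
        assert tree.bp[-1] == 1.0

    def test_bp_in_unit_interval(self, small_expression):
        tree = bootstrap_support(small_expression, nboot=50, seed=2)
        assert ((tree.bp >= 0) & (tree.bp <= 1)).all()


class TestAuPvalues:
    def test_planted_module_high_au(self, small_expression):
        tree = au_pvalues(small_expression, nboot_per_scale=100, seed=3)
        sets = tree.leaf_sets()
        module_a = frozenset(f"a{i}" for i in range(4))
        au = {sets[k]: tree.au[k] for k in range(len(sets))}
        assert au[module_a] >= 0.95

    def test_degenerate_bp_one(self):
        # two exactly duplicated profile groups: module nodes in every replicate
        base = pd.DataFrame(
            {
                "a1": [1.0, 5, 2, 8, 3, 9],
                "a2": [1.1, 5.1, 2.1, 8.1, 3.1, 9.1],
                "b1": [9.0, 2, 8, 1, 7, 0],
                "b2": [9.1, 2.1, 8.1, 1.1, 7.1, 0.1],
            }
        ).T
        tree = au_pvalues(base, nboot_per_scale=30, seed=4)
        sets = tree.leaf_sets()
        idx = sets.index(frozenset({"a1", "a2"}))
        assert tree.au_degenerate[idx]
        assert tree.au[idx] == 1.0
        assert tree.au_se[idx] == 0.0

    def test_au_within_unit_interval(self, small_expression):
        tree = au_pvalues(small_expression, nboot_per_scale=50, seed=5)
        assert ((tree.au >= 0) & (tree.au <= 1)).all()

    def test_needs_two_scales(self, small_expression):
        with pytest.raises(ClusteringError):
            au_pvalues(small_expression, scale_factors=(1.0,))

    def test_reproducible(self, small_expression):
        t1 = au_pvalues(small_expression, nboot_per_scale=30, seed=7)
        t2 = au_pvalues(small_expression, nboot_per_scale=30, seed=7)
        assert np.array_equal(t1.au, t2.au)


class TestSignificantClusters:
    def make_tree_with_au(self, au_values, values):
        tree = tree_from_values(values)
        tree.au = np.asarray(au_values, dtype=float)
        tree.bp = tree.au.copy()
        return tree

    def test_no_passing_nodes(self, small_expression):
        tree = self.make_tree_with_au(
            np.zeros(small_expression.shape[0] - 1), small_expression
        )
        assert significant_clusters(tree) == []

    def test_nested_passing_reports_ancestor_only(self):
        # 6 leaves; force AU so a child and its ancestor both pass
        values = pd.DataFrame(
            np.random.default_rng(16).standard_normal((6, 8)),
            index=[f"g{i}" for i in range(6)],
        )
        tree = tree_from_values(values)
        masks = tree.node_masks()
        au = np.zeros(len(masks))
        # find a nested pair by enumeration
        child, parent = next(
            (i, j)
            for i in range(len(masks))
            for j in range(len(masks))
            if i != j and masks[i] & masks[j] == masks[i]
        )
        au[child] = 0.99
        au[parent] = 0.97
        tree.au = au
        tree.bp = au.copy()
        clusters = significant_clusters(tree, alpha=0.95)
        leaf_sets = tree.leaf_sets()
        assert leaf_sets[parent] in [c.genes for c in clusters]
        assert leaf_sets[child] not in [c.genes for c in clusters]

    def test_alpha_zero_returns_root(self, small_expression):
        tree = self.make_tree_with_au(
            np.zeros(small_expression.shape[0] - 1), small_expression
        )
        clusters = significant_clusters(tree, alpha=0.0)
        assert len(clusters) == 1
        assert clusters[0].genes == frozenset(small_expression.index)

    def test_requires_au(self, small_expression):
        tree = tree_from_values(small_expression)
        with pytest.raises(ClusteringError):
            significant_clusters(tree)


class TestTreeOutput:
    def test_newick_parses(self, small_expression):
        tree = au_pvalues(small_expression, nboot_per_scale=20, seed=8)
        newick = tree.to_newick()
        assert newick.endswith(";")
        assert newick.count("(") == newick.count(")")
        for leaf in small_expression.index:
            assert leaf in newick

    def test_support_table_shape(self, small_expression):
        tree = au_pvalues(small_expression, nboot_per_scale=20, seed=9)
        table = support_table(tree)
        assert len(table) == small_expression.shape[0] - 1
        assert {"au", "bp", "members", "height"} <= set(table.columns)
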