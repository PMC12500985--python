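import itertools

import numpy as np
import pandas as pd
import pytest

from droughtrank.clustering import cluster_genotypes, heatmap_matrix
from droughtrank.errors import ParameterError


def brute_force_agglomerate(points, linkage="complete"):
    """Exhaustive oracle: recompute every cluster-pair distance from raw
    points at every step and merge the global minimum."""
    n = len(points)
    D = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            pair_d = [D[i, j] for i in a for j in b]
            d = max(pair_d) if linkage == "complete" else float(np.mean(pair_d))
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return merges


class TestAgglomeration:
    def test_hand_computed_line_example(self):
        # colinear points 0, 1, 3.5, 8: merges at complete-linkage heights
        # 1 ({0,1}), 3.5 ({0,1}+{3.5}), 8 (all)
        X = np.array([[0.0], [1.0], [3.5], [8.0]])
        g = cluster_genotypes(X, ["a", "b", "c", "d"], k=2)
        got = [(frozenset(la), frozenset(lb), h) for la, lb, h in g.merges]
        assert got[0][:2] in ({frozenset({0}), frozenset({1})},) or {
            got[0][0],
            got[0][1],
        } == {frozenset({0}), frozenset({1})}
        np.testing.assert_allclose(g.heights, [1.0, 3.5, 8.0])
        assert {got[1][0], got[1][1]} == {frozenset({0, 1}), frozenset({2})}
        assert list(g.labels) == [1, 1, 2, 2] or list(g.labels) == [1, 1, 1, 2]

    @pytest.mark.parametrize("linkage", ["complete", "average"])
    @pytest.mark.parametrize("seed", range(8))
    def test_brute_force_oracle_up_to_six_points(self, seed, linkage):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        X = rng.standard_normal((n, 3))
        g = cluster_genotypes(X, linkage=linkage, k=1)
        oracle = brute_force_agglomerate(X, linkage)
        assert len(g.merges) == len(oracle)
        for (la, lb, h), (oa, ob, oh) in zip(g.merges, oracle):
            assert {frozenset(la), frozenset(lb)} == {oa, ob}
            assert h == pytest.approx(oh, abs=1e-12)

    def test_heights_monotone_and_rescaled_max_25(self, rng):
        X = rng.standard_normal((12, 4))
        g = cluster_genotypes(X, k=3)
        assert (np.diff(g.heights) >= -1e-12).all()
        assert g.rescaled_heights.max() == pytest.approx(25.0)
        assert (g.rescaled_heights >= 0).all()

    def test_two_planted_blobs_recovered(self, rng):
        a = rng.normal(0, 0.1, size=(6, 2))
        b = rng.normal(10, 0.1, size=(5, 2))
        X = np.vstack([a, b])
        g = cluster_genotypes(X, k=2)
        labels = np.asarray(g.labels)
        assert len(set(labels[:6])) == 1
        assert len(set(labels[6:])) == 1
        assert labels[0] != labels[-1]

    def test_row_order_invariance(self, rng):
        X = rng.standard_normal((9, 3))
        names = [f"g{i}" for i in range(9)]
        g1 = cluster_genotypes(X, names, k=3)
        perm = rng.permutation(9)
        g2 = cluster_genotypes(X[perm], [names[i] for i in perm], k=3)
        m1 = [
            {frozenset(g1.genotypes[i] for i in la), frozenset(g1.genotypes[i] for i in lb)}
            for la, lb, _ in g1.merges
        ]
        m2 = [
            {frozenset(g2.genotypes[i] for i in la), frozenset(g2.genotypes[i] for i in lb)}
            for la, lb, _ in g2.merges
        ]
        assert m1 == m2
        by1, by2 = g1.labels_by_name(), g2.labels_by_name()
        # same partition (group ids may be renumbered)
        part1 = {frozenset(k for k, v in by1.items() if v == g) for g in set(by1.values())}
        part2 = {frozenset(k for k, v in by2.items() if v == g) for g in set(by2.values())}
        assert part1 == part2

    def test_rotation_invariance_of_labels(self, rng):
        X = rng.standard_normal((10, 2))
        theta = 0.83
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        g1 = cluster_genotypes(X, k=3)
        g2 = cluster_genotypes(X @ R.T, k=3)
        np.testing.assert_allclose(g1.heights, g2.heights, atol=1e-9)
        np.testing.assert_array_equal(g1.labels, g2.labels)

    def test_cut_by_rescaled_height(self, rng):
        X = rng.standard_normal((8, 2))
        full = cluster_genotypes(X, k=1)
        # just below the top merge (25): everything but the final join applies
        g = cluster_genotypes(X, k=None, rescaled_height=25.0 - 1e-9)
        assert g.k == 2
        # just below the second-highest merge: three groups remain
        g3 = cluster_genotypes(
            X, k=None, rescaled_height=full.rescaled_heights[-2] - 1e-9
        )
        assert g3.k == 3

    def test_bad_k(self, rng):
        X = rng.standard_normal((4, 2))
        with pytest.raises(ParameterError):
            cluster_genotypes(X, k=5)
        with pytest.raises(ParameterError):
            cluster_genotypes(X, k=0)

    def test_matches_scipy_heights(self, rng):
        from scipy.cluster.hierarchy import linkage as scipy_linkage

        X = rng.standard_normal((15, 4))
        g = cluster_genotypes(X, k=1)
        Z = scipy_linkage(X, method="complete")
        np.testing.assert_allclose(np.sort(g.heights), np.sort(Z[:, 2]), atol=1e-9)


class TestNewick:
    def test_newick_parses_and_leaf_set(self, rng, tmp_path):
        import dendropy

        X = rng.standard_normal((7, 3))
        names = [f"S{i+1}" for i in range(7)]
        g = cluster_genotypes(X, names, k=3)
        path = tmp_path / "tree.nwk"
        nwk = g.to_newick(path)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(names)
        # root depth equals the rescaled maximum
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        assert max(depths) == pytest.approx(25.0, abs=1e-4)


class TestHeatmap:
    def test_rows_standardized(self, rng):
        X = pd.DataFrame(
            rng.standard_normal((6, 4)),
            index=[f"g{i}" for i in range(6)],
            columns=list("wxyz"),
        )
        M, row_order, col_order = heatmap_matrix(X)
        np.testing.assert_allclose(M.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(M.std(axis=1, ddof=1), 1.0, atol=1e-12)
        assert sorted(col_order) == sorted(X.index)
        assert sorted(row_order) == sorted(X.columns)

    def test_constant_row_zeroed_with_warning(self, rng):
        X = pd.DataFrame(
            {"a": rng.standard_normal(5), "flat": np.full(5, 3.0)},
            index=[f"g{i}" for i in range(5)],
        )
        with pytest.warns(UserWarning, match="flat"):
            M, _, _ = heatmap_matrix(X)
        np.testing.assert_array_equal(M.loc["flat"], 0.0)
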