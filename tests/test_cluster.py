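"""Correlation-distance WPGMA clustering, composites and group tests."""

import numpy as np
import pandas as pd
import pytest

from traitspace.cluster import (
    ClusterAssignment,
    ClusterError,
    Dendrogram,
    DistanceMatrix,
    composite_scores,
    correlation_distance,
    cut_tree,
    group_correlation,
    paired_ttest,
    wpgma_linkage,
)


from oracles import naive_wpgma


class TestCorrelationDistance:
    def test_identical_and_negated_profiles(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        X = np.vstack([x, x, -x])
        d = correlation_distance(X, axis="rows").values
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        X = rng.standard_normal((6, 30))
        d = correlation_distance(X, axis="rows").values
        for i in range(6):
            for j in range(6):
                r = np.corrcoef(X[i], X[j])[0, 1]
                assert d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_axis_columns_transposes(self, rng):
        X = rng.standard_normal((20, 4))
        d1 = correlation_distance(X, axis="columns").values
        d2 = correlation_distance(X.T, axis="rows").values
        assert np.allclose(d1, d2)

    def test_constant_profile_errors(self):
        X = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ClusterError, match="constant"):
            correlation_distance(X, axis="rows")


class TestWPGMA:
    def test_three_point_hand_example(self):
        D = DistanceMatrix(("a", "b", "c"), np.array([[0, 0.1, 1.0], [0.1, 0, 1.0], [1.0, 1.0, 0]]))
        dend = wpgma_linkage(D)
        assert dend.merges[0] == (0, 1, pytest.approx(0.1))
        # weighted update: d((ab), c) = (1 + 1)/2 = 1
        assert dend.merges[1][2] == pytest.approx(1.0)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(6, 9))
            X = rng.standard_normal((n, 12))
            D = correlation_distance(X, axis="rows")
            dend = wpgma_linkage(D)
            oracle = naive_wpgma(D.values)
            for (a, b, h), (oa, ob, oh) in zip(dend.merges, oracle):
                assert (a, b) == (oa, ob)
                assert h == pytest.approx(oh, abs=1e-12)

    def test_matches_scipy_weighted_heights(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(123)
        X = rng.standard_normal((8, 15))
        D = correlation_distance(X, axis="rows")
        ours = wpgma_linkage(D).to_scipy()
        theirs = linkage(squareform(D.values, checks=False), method="weighted")
        assert np.allclose(np.sort(ours[:, 2]), np.sort(theirs[:, 2]), atol=1e-10)

    def test_label_permutation_same_tree(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((7, 20))
        D = correlation_distance(X, axis="rows")
        dend = wpgma_linkage(D)
        perm = rng.permutation(7)
        Dp = DistanceMatrix(
            tuple(D.labels[i] for i in perm), D.values[np.ix_(perm, perm)]
        )
        dend_p = wpgma_linkage(Dp)
        # same merge heights, same leaf partition at every level
        assert np.allclose(
            sorted(h for *_, h in dend.merges), sorted(h for *_, h in dend_p.merges)
        )
        for k in range(1, 8):
            a = cut_tree(dend, k)
            b = cut_tree(dend_p, k)
            part_a = {frozenset(a.members(c)) for c in range(1, k + 1)}
            part_b = {frozenset(b.members(c)) for c in range(1, k + 1)}
            assert part_a == part_b

    def test_newick_parses_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(8)
        D = correlation_distance(rng.standard_normal((5, 10)), axis="rows")
        nwk = wpgma_linkage(D).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert len(tree.leaf_nodes()) == 5


class TestCutTree:
    def _dend(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        return wpgma_linkage(correlation_distance(rng.standard_normal((n, 12)), axis="rows"))

    def test_extremes(self):
        dend = self._dend()
        assert cut_tree(dend, 1).k == 1
        singles = cut_tree(dend, 6)
        assert sorted(singles.mapping.values()) == [1, 2, 3, 4, 5, 6]

    def test_planted_two_blocks_recovered(self):
        D = np.full((6, 6), 1.8)
        D[:3, :3] = 0.1
        D[3:, 3:] = 0.1
        np.fill_diagonal(D, 0.0)
        dend = wpgma_linkage(DistanceMatrix(tuple("abcdef"), D))
        cut = cut_tree(dend, 2)
        assert {frozenset(cut.members(1)), frozenset(cut.members(2))} == {
            frozenset("abc"),
            frozenset("def"),
        }

    def test_out_of_range_k(self):
        with pytest.raises(ClusterError):
            cut_tree(self._dend(), 7)


class TestComposites:
    def test_mean_of_members_identity(self, rng):
        z = pd.DataFrame(rng.standard_normal((10, 4)), columns=list("abcd"))
        assign = ClusterAssignment({"a": 1, "b": 1, "c": 2, "d": 2}, 2)
        comps = composite_scores(z, assign)
        assert np.allclose(comps["cluster_1"], z[["a", "b"]].mean(axis=1))
        assert np.allclose(comps["cluster_2"], z[["c", "d"]].mean(axis=1))

    def test_single_trait_cluster(self, rng):
        z = pd.DataFrame(rng.standard_normal((5, 2)), columns=["a", "b"])
        comps = composite_scores(z, ClusterAssignment({"a": 1, "b": 2}, 2))
        assert np.allclose(comps["cluster_1"], z["a"])

    def test_zero_scores(self):
        z = pd.DataFrame(np.zeros((4, 3)), columns=list("abc"))
        comps = composite_scores(z, ClusterAssignment({"a": 1, "b": 1, "c": 2}, 2))
        assert (comps.to_numpy() == 0).all()


class TestPairedTTest:
    def test_equal_inputs(self):
        x = np.arange(5.0)
        t, df, p = paired_ttest(x, x)
        assert (t, df, p) == (0.0, 4, 1.0)

    def test_df_is_n_minus_one(self, rng):
        x = rng.standard_normal(328)
        y = rng.standard_normal(328)
        _, df, _ = paired_ttest(x, y)
        assert df == 327

    def test_matches_textbook_formula(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40) + 0.3
        t, df, p = paired_ttest(x, y)
        d = x - y
        t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_direct, abs=1e-12)

    def test_too_short(self):
        with pytest.raises(ClusterError):
            paired_ttest([1.0], [2.0])


class TestGroupCorrelation:
    def _groups(self, sizes):
        mapping = {}
        g = 1
        i = 0
        for s in sizes:
            for _ in range(s):
                mapping[f"S{i}"] = g
                i += 1
            g += 1
        return ClusterAssignment(mapping, len(sizes))

    def test_perfect_anticorrelation(self, rng):
        idx = [f"S{i}" for i in range(6)]
        pos = pd.Series(rng.standard_normal(6), index=idx)
        neg = -pos
        out = group_correlation(pos, neg, self._groups([3, 3]))
        assert np.allclose(out["r"], -1.0)

    def test_independent_composites_near_zero(self):
        rng = np.random.default_rng(21)
        idx = [f"S{i}" for i in range(5000)]
        pos = pd.Series(rng.standard_normal(5000), index=idx)
        neg = pd.Series(rng.standard_normal(5000), index=idx)
        out = group_correlation(pos, neg, self._groups([5000]))
        assert abs(out.loc[1, "r"]) < 0.05

    def test_matches_direct_computation(self):
        idx = [f"S{i}" for i in range(4)]
        pos = pd.Series([1.0, 2.0, 4.0, 3.0], index=idx)
        neg = pd.Series([2.0, 1.0, 3.0, 5.0], index=idx)
        out = group_correlation(pos, neg, self._groups([4]))
        assert out.loc[1, "r"] == pytest.approx(np.corrcoef(pos, neg)[0, 1], abs=1e-12)

    def test_small_group_errors(self, rng):
        idx = [f"S{i}" for i in range(3)]
        pos = pd.Series(rng.standard_normal(3), index=idx)
        with pytest.raises(ClusterError, match="fewer than 3"):
            group_correlation(pos, pos * 2, self._groups([2, 1]))
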