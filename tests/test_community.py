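import io
import itertools

import numpy as np
import pandas as pd
import pytest
import skbio

from agpms import community as cm
from agpms.core import FeatureTable


def make_table(mat, features, samples, kind="otu_counts"):
    return FeatureTable(pd.DataFrame(mat, index=features, columns=samples), kind=kind)


class TestShannon:
    def test_uniform_four_features(self):
        ft = make_table([[10], [10], [10], [10]], list("abcd"), ["s"])
        assert cm.shannon(ft).loc["s"] == pytest.approx(2.0)

    def test_single_feature_zero(self):
        ft = make_table([[7], [0], [0]], list("abc"), ["s"])
        assert cm.shannon(ft).loc["s"] == pytest.approx(0.0)

    def test_direct_summation(self):
        ft = make_table([[1], [2], [3]], list("abc"), ["s"])
        p = np.array([1, 2, 3]) / 6
        expected = -(p * np.log2(p)).sum()
        assert cm.shannon(ft).loc["s"] == pytest.approx(expected)

    def test_all_zero_sample_errors(self):
        ft = make_table([[1, 0], [1, 0]], list("ab"), ["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            cm.shannon(ft)

    def test_uniform_maximizes_at_fixed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 50, size=5)
            ft = make_table(
                np.column_stack([counts, np.full(5, 10)]),
                list("abcde"), ["ragged", "uniform"],
            )
            h = cm.shannon(ft)
            assert h["uniform"] >= h["ragged"] - 1e-12


class TestRarefy:
    def test_identity_at_exact_depth(self):
        ft = make_table([[3], [4], [5]], list("abc"), ["s"])
        out = cm.rarefy(ft, depth=12, seed=0)
        np.testing.assert_array_equal(out.values().ravel(), [3, 4, 5])

    def test_depth_one(self):
        ft = make_table([[5, 2], [5, 9]], list("ab"), ["s1", "s2"])
        out = cm.rarefy(ft, depth=1, seed=1)
        np.testing.assert_array_equal(out.values().sum(axis=0), [1, 1])
        assert ((out.values() == 0) | (out.values() == 1)).all()

    def test_hypergeometric_expectation(self):
        """[50, 50] rarefied to 10: mean count of feature 1 is ~5."""
        ft = make_table(
            np.tile([[50], [50]], (1, 1500)), ["f1", "f2"],
            [f"s{i}" for i in range(1500)],
        )
        out = cm.rarefy(ft, depth=10, seed=3)
        assert out.data.loc["f1"].mean() == pytest.approx(5.0, abs=0.15)

    def test_shallow_samples_dropped_with_warning(self):
        ft = make_table([[10, 1], [10, 1]], list("ab"), ["deep", "shallow"])
        with pytest.warns(UserWarning, match="shallow"):
            out = cm.rarefy(ft, depth=15, seed=0)
        assert out.samples == ["deep"]

    def test_depth_exceeding_all_errors(self):
        ft = make_table([[2], [2]], list("ab"), ["s"])
        with pytest.raises(ValueError):
            cm.rarefy(ft, depth=100, seed=0)


class TestWeightedUnifrac:
    def tree(self, newick):
        return skbio.TreeNode.read(io.StringIO(newick))

    def test_identical_samples_zero(self):
        tree = self.tree("(A:1,B:2);")
        ft = make_table([[3, 3], [5, 5]], ["A", "B"], ["s1", "s2"])
        dm = cm.weighted_unifrac(ft, tree)
        assert dm["s1", "s2"] == pytest.approx(0.0)

    def test_two_leaf_hand_value(self):
        """All mass on opposite unit branches: raw distance 1 + 1 = 2."""
        tree = self.tree("(A:1,B:1);")
        ft = make_table([[10, 0], [0, 10]], ["A", "B"], ["s1", "s2"])
        dm = cm.weighted_unifrac(ft, tree)
        assert dm["s1", "s2"] == pytest.approx(2.0)

    def test_three_leaf_hand_value(self):
        """X all on A; Y split 50/50 between B and C.

        Branches: A(1.0)*|1-0| + B(1.0)*|0-0.5| + internal(0.5)*|1-0.5|
        + C(2.0)*|0-0.5| = 1 + 0.5 + 0.25 + 1 = 2.75.
        """
        tree = self.tree("((A:1,B:1):0.5,C:2);")
        ft = make_table([[8, 0], [0, 4], [0, 4]], ["A", "B", "C"], ["X", "Y"])
        dm = cm.weighted_unifrac(ft, tree)
        assert dm["X", "Y"] == pytest.approx(2.75)

    def test_normalized_bounded_by_one(self):
        tree = self.tree("(A:1,B:1);")
        ft = make_table([[10, 0], [0, 10]], ["A", "B"], ["s1", "s2"])
        dm = cm.weighted_unifrac(ft, tree, normalized=True)
        assert dm["s1", "s2"] == pytest.approx(1.0)

    def test_feature_order_invariance(self, community):
        table, _, tree, _ = community
        sub = table.filter_samples(table.samples[:6])
        dm1 = cm.weighted_unifrac(sub, tree)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sub.features))
        shuffled = FeatureTable(sub.data.iloc[perm], kind=sub.kind)
        dm2 = cm.weighted_unifrac(shuffled, tree)
        np.testing.assert_allclose(dm1.data, dm2.data, atol=1e-12)

    def test_missing_feature_errors(self):
        tree = self.tree("(A:1,B:1);")
        ft = make_table([[1, 2], [3, 4]], ["A", "Z"], ["s1", "s2"])
        with pytest.raises(ValueError, match="Z"):
            cm.weighted_unifrac(ft, tree)

    def test_matches_skbio(self, community):
        table, _, tree, _ = community
        sub = table.filter_samples(table.samples[:8])
        dm = cm.weighted_unifrac(sub, tree)
        ref = skbio.diversity.beta_diversity(
            "weighted_unifrac",
            sub.values().T.astype(int),
            ids=sub.samples,
            taxa=sub.features,
            tree=tree,
        )
        np.testing.assert_allclose(dm.data, ref.data, atol=1e-10)


class TestPermanova:
    @staticmethod
    def brute_force_oneway(dm, labels):
        """Classic one-way pseudo-F with full permutation enumeration."""
        D2 = dm.data**2
        n = len(labels)
        labels = np.asarray(labels)

        def pseudo_f(lbls):
            sst = D2[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for g in np.unique(lbls):
                idx = np.where(lbls == g)[0]
                ssw += D2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
            ssb = sst - ssw
            a = len(np.unique(lbls))
            return (ssb / (a - 1)) / (ssw / (n - a))

        f_obs = pseudo_f(labels)
        perms = [np.array(p) for p in set(itertools.permutations(labels))]
        count = sum(pseudo_f(p) >= f_obs - 1e-12 for p in perms)
        return f_obs, count / len(perms)

    def test_matches_brute_force_enumeration(self):
        """Sequential PERMANOVA with a single two-level term reproduces the
        classic one-way pseudo-F, and the permutation p matches complete
        enumeration on 8 samples."""
        rng = np.random.default_rng(42)
        pts = np.vstack([rng.normal(0, 1, (4, 2)), rng.normal(1.5, 1, (4, 2))])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(8)]
        dm = skbio.DistanceMatrix(D, ids=ids)
        md = pd.DataFrame(
            {"diet": ["corn"] * 4 + ["wheat"] * 4,
             "agp": [False] * 8, "age_days": [10] * 8,
             "site": ["ceca"] * 8, "bird_id": ids},
            index=ids,
        )
        f_brute, p_brute = self.brute_force_oneway(dm, md["diet"].to_numpy())
        res = cm.permanova(dm, md, ["diet"], n_perm=9999, seed=0)[0]
        assert res.statistic == pytest.approx(f_brute, rel=1e-9)
        assert res.p == pytest.approx(p_brute, abs=0.02)

    def test_perfect_separation_r2_one(self):
        pts = np.array([[0.0], [0.0], [0.0], [5.0], [5.0], [5.0]])
        D = np.abs(pts - pts.T)
        ids = [f"s{i}" for i in range(6)]
        dm = skbio.DistanceMatrix(D, ids=ids)
        md = pd.DataFrame({"grp": list("aaabbb")}, index=ids)
        res = cm.permanova(dm, md, ["grp"], n_perm=99, seed=0)[0]
        assert res.r2 == pytest.approx(1.0)

    def test_permutation_p_floor(self):
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(9, 0.1, (5, 2))])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(10)]
        dm = skbio.DistanceMatrix(D, ids=ids)
        md = pd.DataFrame({"grp": list("aaaaabbbbb")}, index=ids)
        res = cm.permanova(dm, md, ["grp"], n_perm=99, seed=0)[0]
        assert res.p == pytest.approx(1 / 100)

    def test_single_level_factor_errors(self):
        ids = list("abcd")
        dm = skbio.DistanceMatrix(1 - np.eye(4), ids=ids)
        md = pd.DataFrame({"grp": ["x"] * 4}, index=ids)
        with pytest.raises(ValueError, match="single level"):
            cm.permanova(dm, md, ["grp"], n_perm=9, seed=0)

    def test_sequential_r2_sums_with_residual(self, community):
        table, _, tree, truth = community
        md = truth.extras["metadata"]
        dm = cm.weighted_unifrac(table, tree)
        res = cm.permanova(dm, md, ["agp", "diet", "diet:agp"], n_perm=49, seed=1)
        assert sum(r.r2 for r in res) <= 1 + 1e-9

    def test_matches_skbio_single_term(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(12)]
        dm = skbio.DistanceMatrix(D, ids=ids)
        labels = ["a"] * 6 + ["b"] * 6
        md = pd.DataFrame({"grp": labels}, index=ids)
        ours = cm.permanova(dm, md, ["grp"], n_perm=999, seed=0)[0]
        ref = skbio.stats.distance.permanova(dm, grouping=labels, permutations=999)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-9)


class TestPermdisp:
    def test_degenerate_identical_groups(self):
        pts = np.array([0.0, 0.0, 0.0, 4.0, 4.0, 4.0])[:, None]
        D = np.abs(pts - pts.T)
        ids = [f"s{i}" for i in range(6)]
        dm = skbio.DistanceMatrix(D, ids=ids)
        with pytest.warns(UserWarning, match="undefined"):
            res = cm.permdisp(dm, list("aaabbb"), n_perm=99, seed=0)
        assert res.p == 1.0

    def test_planted_dispersion_detected(self):
        rng = np.random.default_rng(11)
        tight = rng.normal(0, 0.1, (10, 2))
        loose = rng.normal(0, 1.0, (10, 2)) * 10
        pts = np.vstack([tight, loose])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(20)]
        dm = skbio.DistanceMatrix(D, ids=ids)
        res = cm.permdisp(dm, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=0)
        assert res.p < 0.01

    def test_group_of_one_errors(self):
        dm = skbio.DistanceMatrix(1 - np.eye(3), ids=list("abc"))
        with pytest.raises(ValueError):
            cm.permdisp(dm, ["a", "b", "b"], n_perm=9, seed=0)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 1, (8, 3)), rng.normal(0, 3, (8, 3))])
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(16)]
        dm = skbio.DistanceMatrix(D, ids=ids)
        labels = ["a"] * 8 + ["b"] * 8
        ours = cm.permdisp(dm, labels, n_perm=499, seed=0)
        ref = skbio.stats.distance.permdisp(
            dm, grouping=labels, permutations=499, test="centroid"
        )
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-6)


class TestMetricProperties:
    def test_unifrac_metric_on_random_instances(self):
        """Raw weighted UniFrac: symmetry, zero diagonal, triangle inequality."""
        from agpms.synthetic import SimulationDesign, simulate_community

        for seed in range(5):
            d = SimulationDesign(n_taxa=10, n_birds_per_arm=1, seed=seed)
            table, _, tree, _ = simulate_community(d)
            sub = table.filter_samples(table.samples[:6])
            dm = cm.weighted_unifrac(sub, tree)
            D = dm.data
            assert np.allclose(D, D.T, atol=1e-12)
            assert np.allclose(np.diag(D), 0)
            n = D.shape[0]
            for i, j, k in itertools.permutations(range(n), 3):
                assert D[i, j] <= D[i, k] + D[k, j] + 1e-9
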