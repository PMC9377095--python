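import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from agpms import differential as da
from agpms.core import FeatureTable


def make_table(mat, features=None, samples=None, kind="otu_counts"):
    mat = np.asarray(mat)
    features = features or [f"f{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{j}" for j in range(mat.shape[1])]
    return FeatureTable(pd.DataFrame(mat, index=features, columns=samples), kind=kind)


class TestPoscounts:
    def test_identical_samples(self):
        ft = make_table([[4, 4], [9, 9]])
        np.testing.assert_allclose(da.poscounts_size_factors(ft), [1, 1])

    def test_pure_depth_doubling(self):
        ft = make_table([[4, 8], [10, 20], [3, 6]])
        sf = da.poscounts_size_factors(ft)
        assert sf["s1"] / sf["s0"] == pytest.approx(2.0)

    def test_structural_zero_hand_computation(self):
        """3x3 with one zero: reference uses positive counts only."""
        counts = np.array([[2.0, 4.0, 8.0], [3.0, 0.0, 3.0], [5.0, 5.0, 5.0]])
        ft = make_table(counts)
        # feature references: geometric means over positive entries
        ref = np.array(
            [np.exp(np.mean(np.log([2, 4, 8]))),
             np.exp(np.mean(np.log([3, 3]))),
             5.0]
        )
        raw = []
        for j in range(3):
            col = counts[:, j]
            ratios = col[col > 0] / ref[col > 0]
            raw.append(np.median(ratios))
        expected = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(da.poscounts_size_factors(ft), expected)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(20, size=(30, 6)).astype(float)
        counts[counts == 0] = 1
        ft = make_table(counts)
        sf = da.poscounts_size_factors(ft)
        scaled = counts.copy()
        scaled[:, 2] *= 3
        sf2 = da.poscounts_size_factors(make_table(scaled))
        ratio = (sf2 / sf).to_numpy()
        # sample 3's factor grows 3x relative to the others
        assert ratio[2] / ratio[0] == pytest.approx(3.0, rel=1e-9)

    def test_all_zero_sample_errors(self):
        ft = make_table([[1, 0], [2, 0]])
        with pytest.raises(ValueError):
            da.poscounts_size_factors(ft)


class TestFilterFeatures:
    def test_otu_relabund_drops_rare(self):
        # grand total 100000; feature at 4 counts = 0.004% < 0.005%
        counts = np.zeros((2, 4))
        counts[0] = [24999, 25000, 25000, 24997]
        counts[1] = [4, 0, 0, 0]
        out, removed = da.filter_features(
            make_table(counts), "otu_relabund", return_removed=True
        )
        assert removed == ["f1"]

    def test_lrt_prevalence_boundary_kept(self):
        # >= 5 counts in exactly 4 samples: kept
        counts = np.array([[5, 5, 5, 5, 0, 0], [5, 5, 5, 4, 0, 0]])
        out = da.filter_features(make_table(counts), "lrt_prevalence")
        assert out.features == ["f0"]

    def test_transcript_min_reads(self):
        counts = np.array([[4, 0], [3, 2]])
        out = da.filter_features(make_table(counts), "transcript_min_reads")
        assert out.features == ["f1"]

    def test_empty_in_empty_out(self):
        ft = make_table(np.empty((0, 3)))
        out = da.filter_features(ft, "otu_relabund")
        assert out.shape == (0, 3)


class TestNBGLM:
    def test_identical_groups_zero_coefficient(self):
        y = np.array([5, 7, 9, 5, 7, 9])
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        res = da.NBGLM(y, X).fit()
        assert abs(res.params[1]) < 1e-6

    def test_intercept_only_closed_form(self):
        """With a common offset the NB2 MLE of the mean is the sample mean."""
        y = np.array([3, 8, 1, 12, 6, 4])
        X = np.ones((6, 1))
        res = da.NBGLM(y, X).fit(alpha=0.3)
        assert np.exp(res.params[0]) == pytest.approx(y.mean(), rel=1e-6)

    def test_intercept_only_poisson_offset_closed_form(self):
        """Poisson limit with offsets: exp(b0) = sum(y) / sum(sf)."""
        y = np.array([10, 30, 15, 22])
        sf = np.array([0.5, 2.0, 1.0, 1.5])
        res = da.NBGLM(y, np.ones((4, 1)), offset=np.log(sf)).fit(alpha=1e-12)
        assert np.exp(res.params[0]) == pytest.approx(y.sum() / sf.sum(), rel=1e-6)

    def test_poisson_limit_matches_poisson_glm(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(40), rng.integers(0, 2, 40)])
        y = rng.poisson(np.exp(1.0 + 0.7 * X[:, 1]))
        ours = da.NBGLM(y, X).fit(alpha=1e-10)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-5)

    def test_fixed_alpha_matches_statsmodels_nb(self):
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(60), rng.integers(0, 2, 60)])
        mu = np.exp(2.0 + 0.5 * X[:, 1])
        r = 1 / 0.2
        y = rng.negative_binomial(r, r / (r + mu))
        ours = da.NBGLM(y, X).fit(alpha=0.2)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=0.2)).fit()
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)
        assert ours.llf == pytest.approx(ref.llf, rel=1e-8)

    def test_alpha_floors_on_poisson_data(self):
        rng = np.random.default_rng(6)
        y = rng.poisson(200, size=200)
        res = da.NBGLM(y, np.ones((200, 1))).fit()
        assert res.alpha < 0.01

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError, match="rank"):
            da.NBGLM(np.arange(4), X)


@pytest.fixture(scope="module")
def small_community():
    from agpms.synthetic import SimulationDesign, simulate_community

    d = SimulationDesign(n_taxa=25, seed=21)
    table, _, _, truth = simulate_community(d)
    return table, truth


@pytest.fixture(scope="module")
def de_table():
    rng = np.random.default_rng(9)
    n = 12
    labels = pd.Series(["ctl"] * 6 + ["trt"] * 6, index=[f"s{i}" for i in range(n)])
    base = rng.lognormal(3, 1, size=30)
    mu = np.tile(base[:, None], (1, n))
    mu[:5, 6:] *= 8  # planted strong upregulation
    mu[5:8, 6:] *= 1.6  # small shift, below the LFC rule
    r = 1 / 0.05
    counts = rng.negative_binomial(r, r / (r + mu))
    return make_table(counts), labels


class TestLRTEffects:
    def test_planted_effects_detected(self, small_community):
        table, truth = small_community
        md = truth.extras["metadata"]
        eff = da.lrt_effects(table, md, "diet_main").set_index("feature_id")
        fc = truth.taxon_log2fc["diet"]
        planted = fc[fc != 0].index
        assert (eff.loc[planted, "q"] < 0.05).mean() >= 0.9

    def test_reparameterization_invariance(self):
        """The LRT statistic is identical under dummy and sum-to-zero coding."""
        rng = np.random.default_rng(8)
        n = 16
        g = np.repeat([0.0, 1.0], 8)
        y = rng.negative_binomial(10, 10 / (10 + 30), size=n)
        ones = np.ones(n)
        for full_cols, red_cols in [
            ((ones, g), (ones,)),
            ((ones, 2 * g - 1), (ones,)),  # effect coding
        ]:
            full = da.NBGLM(y, np.column_stack(full_cols)).fit()
            red = da.NBGLM(y, np.column_stack(red_cols)).fit(alpha=full.alpha)
            stat = 2 * (full.llf - red.llf)
            if full_cols[1][0] == 0:
                stat_dummy = stat
        assert stat == pytest.approx(stat_dummy, abs=1e-6)

    def test_constant_feature_stat_zero(self, small_community):
        table, truth = small_community
        md = truth.extras["metadata"]
        const = table.data.copy()
        const.iloc[0] = 7.0
        eff = da.lrt_effects(
            FeatureTable(const, kind="otu_counts"), md, "diet_main",
            size_factors=pd.Series(1.0, index=table.samples),
        )
        row = eff.set_index("feature_id").iloc[0]
        assert row["lrt_statistic"] == pytest.approx(0.0, abs=1e-4)
        assert row["p"] > 0.99

    def test_missing_level_errors(self, small_community):
        table, truth = small_community
        md = truth.extras["metadata"]
        corn_only = md[md["diet"] == "corn"]
        sub = table.filter_samples(corn_only.index)
        with pytest.raises(ValueError, match="diet"):
            da.lrt_effects(sub, corn_only, "diet_main")


class TestPairwiseDE:
    def test_lfc_rule_transcript_mode(self, de_table):
        table, labels = de_table
        res = da.pairwise_de(table, labels, ("ctl", "trt")).set_index("feature_id")
        strong = res.iloc[:5]
        assert strong["significant"].all()
        small = res.iloc[5:8]
        # below the |log2fc| > 1 rule even when q is small
        assert not (small["significant"] & (small["log2fc"].abs() <= 1)).any()

    def test_otu_mode_ignores_lfc(self, de_table):
        table, labels = de_table
        res_t = da.pairwise_de(table, labels, ("ctl", "trt"), mode="transcript")
        res_o = da.pairwise_de(table, labels, ("ctl", "trt"), mode="otu")
        t = res_t.set_index("feature_id")
        o = res_o.set_index("feature_id")
        borderline = (o["q"] < 0.05) & (t["log2fc"].abs() <= 1)
        assert (o.loc[borderline, "significant"]).all()
        assert not (t.loc[borderline, "significant"]).any()

    def test_identical_groups_null(self):
        counts = np.tile([[10, 12, 9, 11, 10, 12, 9, 11]], (5, 1))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=[f"s{j}" for j in range(8)])
        res = da.pairwise_de(make_table(counts), labels, ("a", "b"))
        assert (res["log2fc"].abs() < 0.2).all()
        assert not res["significant"].any()

    def test_small_group_errors(self, de_table):
        table, labels = de_table
        bad = labels.copy()
        bad.iloc[1:6] = "trt"
        with pytest.raises(ValueError, match="2 samples"):
            da.pairwise_de(table, bad, ("ctl", "trt"))

    def test_significance_thresholds(self):
        """q and |log2fc| gates: q=0.01 & lfc=1.5 passes, lfc=0.5 fails."""
        frame = pd.DataFrame(
            {"feature_id": ["a", "b"], "log2fc": [1.5, 0.5],
             "base_mean": [10, 10], "p": [0.001, 0.001], "q": [0.01, 0.01]}
        )
        sig = (frame["q"] < 0.05) & (frame["log2fc"].abs() > 1)
        assert sig.tolist() == [True, False]
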