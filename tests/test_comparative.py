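"""Cross-clade statistics: ANOVA, REML/ICC, permutation tests, PGLS."""

import numpy as np
import pandas as pd
import pytest

import karyotempo as kt
from karyotempo.comparative import brownian_covariance


def _rate_table(rates):
    return pd.DataFrame({
        "clade": [f"c{i}" for i in range(len(rates))],
        "rate_myr": rates,
        "kingdom": ["K"] * len(rates),
        "higher_taxon": ["T"] * len(rates),
    })


class TestLogRatesAndFoldRange:
    def test_log10_column_and_geometric_mean(self):
        table = kt.log_rates(_rate_table([0.01, 0.1, 1.0]))
        np.testing.assert_allclose(table["log10_rate"], [-2, -1, 0])
        gm = kt.geometric_means(table, "kingdom")
        assert gm["K"] == pytest.approx(0.1)

    def test_single_clade_geometric_mean_is_identity(self):
        gm = kt.geometric_means(_rate_table([0.023]), "kingdom")
        assert gm["K"] == pytest.approx(0.023)

    def test_nonpositive_rate_names_clade(self):
        with pytest.raises(ValueError, match="c1"):
            kt.log_rates(_rate_table([0.1, 0.0]))

    @pytest.mark.parametrize(
        "rates, expected",
        [([0.1, 0.1], 1.0), ([0.001, 0.5], 500.0), ([0.0008, 0.2, 0.7], 875.0)],
    )
    def test_fold_range(self, rates, expected):
        assert kt.fold_range(_rate_table(rates)) == pytest.approx(expected)


class TestAnova:
    def test_hand_computed_example(self):
        # groups (1,2,3) and (4,5,6): MSB = 13.5, MSW = 1 → F = 13.5 on (1,4)
        res = kt.anova_oneway([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert res["F"] == pytest.approx(13.5)
        assert res["df"] == (1, 4)
        assert 0 < res["p_anova"] < 1

    def test_zero_within_variance_gives_infinite_f(self):
        with pytest.warns(UserWarning, match="F reported"):
            res = kt.anova_oneway([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert res["F"] == np.inf

    def test_paper_shaped_df(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=55)
        groups = ["A"] * 43 + ["P"] * 11 + ["F"] * 1
        assert kt.anova_oneway(values, groups)["df"] == (2, 52)

    def test_sum_of_squares_identity(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=40)
        groups = rng.choice(list("abcd"), size=40)
        codes, _ = pd.factorize(groups)
        means = pd.Series(values).groupby(codes).transform("mean").to_numpy()
        ss_total = ((values - values.mean()) ** 2).sum()
        ss_between = ((means - values.mean()) ** 2).sum()
        ss_within = ((values - means) ** 2).sum()
        assert ss_total == pytest.approx(ss_between + ss_within, abs=1e-9)
        # F recomputed from the SS identity matches anova_oneway
        G, N = 4, 40
        F = (ss_between / (G - 1)) / (ss_within / (N - G))
        assert kt.anova_oneway(values, groups)["F"] == pytest.approx(F, abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kt.anova_oneway([1, 2, 3], ["a", "a", "a"])


class TestREML:
    def test_null_data_gives_small_icc(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=54)
        groups = np.repeat(list("abc"), 18)
        res = kt.reml_variance_components(values, groups)
        assert res["icc"] < 0.15

    def test_separated_groups_give_high_icc(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(m, 0.1, size=10) for m in (0, 10, 20)])
        groups = np.repeat(list("abc"), 10)
        res = kt.reml_variance_components(values, groups)
        assert res["icc"] > 0.99

    def test_balanced_case_matches_closed_form(self):
        rng = np.random.default_rng(7)
        n0, G = 8, 6
        values = np.concatenate(
            [rng.normal(rng.normal(0, 1.0), 0.7, size=n0) for _ in range(G)]
        )
        groups = np.repeat([f"g{i}" for i in range(G)], n0)
        a = kt.anova_oneway(values, groups)
        codes, _ = pd.factorize(groups)
        means = np.bincount(codes, weights=values) / n0
        msb = n0 * ((means - values.mean()) ** 2).sum() / (G - 1)
        msw = sum((values[codes == g] - means[g]) @ (values[codes == g] - means[g])
                  for g in range(G)) / (G * (n0 - 1))
        if msb > msw:
            expected_b = (msb - msw) / n0
            res = kt.reml_variance_components(values, groups)
            assert res["sigma2_between"] == pytest.approx(expected_b, abs=1e-6)
            assert res["sigma2_within"] == pytest.approx(msw, abs=1e-6)

    def test_agrees_with_statsmodels_mixedlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        groups = np.repeat([f"g{i}" for i in range(8)], 12)
        values = rng.normal(0, 1, 96) + np.repeat(rng.normal(0, 0.8, 8), 12)
        ours = kt.reml_variance_components(values, groups)
        fit = sm.MixedLM(values, np.ones((96, 1)), groups=groups).fit(reml=True)
        theirs_b = float(np.asarray(fit.cov_re)[0, 0])
        theirs_w = float(fit.scale)
        assert ours["sigma2_between"] == pytest.approx(theirs_b, rel=1e-3, abs=1e-6)
        assert ours["sigma2_within"] == pytest.approx(theirs_w, rel=1e-3)

    def test_boundary_estimate_is_exact_zero(self):
        # groups identical in distribution and tiny between-spread: allow 0
        rng = np.random.default_rng(9)
        values = rng.normal(size=30)
        groups = np.tile(list("abc"), 10)
        res = kt.reml_variance_components(values, groups)
        assert res["sigma2_between"] >= 0.0
        assert res["icc"] == pytest.approx(
            res["sigma2_between"] / (res["sigma2_between"] + res["sigma2_within"])
        )


class TestPermutationTest:
    def test_minimum_attainable_p(self):
        # perfectly separated groups, large n: no permutation can match
        values = np.concatenate([np.arange(20), 100 + np.arange(20)])
        groups = np.repeat(["a", "b"], 20)
        p = kt.permutation_test(values, groups, "F", n_perm=9999, seed=0)
        assert p == pytest.approx(1.0 / 10000.0)

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError):
            kt.permutation_test([1.0, 2.0, 3.0], ["a", "a", "a"], n_perm=99)

    def test_invariant_under_monotone_transform_of_statistic(self):
        # p depends only on the ordering the statistic induces: F vs ICC orderings
        # differ, but F vs F on rescaled values must match exactly
        rng = np.random.default_rng(10)
        values = rng.normal(size=24)
        groups = np.repeat(list("abcd"), 6)
        p1 = kt.permutation_test(values, groups, "F", n_perm=499, seed=3)
        p2 = kt.permutation_test(values * 10 + 5, groups, "F", n_perm=499, seed=3)
        assert p1 == p2

    def test_small_n_perm_rejected(self):
        with pytest.raises(ValueError):
            kt.permutation_test([1, 2, 3, 4], ["a", "a", "b", "b"], n_perm=50)


class TestVarianceDecomposition:
    def test_consistency_of_icc_and_pct(self):
        table, _ = kt.make_clade_rate_table(4, 10, sd_between=0.4, sd_within=0.4, seed=11)
        res = kt.variance_decomposition(table, "higher_taxon", n_perm=199, seed=0)
        assert res.pct_between == pytest.approx(100 * res.icc)
        assert 0 <= res.icc <= 1
        assert 0 < res.p_perm <= 1


class TestPGLS:
    def test_star_tree_equals_ols(self):
        labels = [f"s{i}" for i in range(12)]
        newick = "(" + ",".join(f"{l}:1" for l in labels) + ");"
        tree = kt.read_tree(newick)
        rng = np.random.default_rng(12)
        x = pd.Series(rng.normal(size=12), index=labels)
        y = pd.Series(2.0 * x + rng.normal(size=12), index=labels)
        res = kt.pgls(y, x, tree)
        X = np.column_stack([np.ones(12), x[labels]])
        beta_ols = np.linalg.lstsq(X, y[labels].to_numpy(), rcond=None)[0]
        assert res.slope == pytest.approx(beta_ols[1], abs=1e-10)
        assert res.intercept == pytest.approx(beta_ols[0], abs=1e-10)

    def test_brownian_covariance_structure(self):
        tree = kt.read_tree("((A:1,B:1):1,C:2);")
        V = brownian_covariance(tree, ["A", "B", "C"])
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        np.testing.assert_allclose(V, expected)

    def test_constant_x_rejected(self):
        tree = kt.read_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="singular"):
            kt.pgls(pd.Series([1.0, 2.0, 3.0], index=list("ABC")),
                    pd.Series([1.0, 1.0, 1.0], index=list("ABC")), tree)

    def test_slope_recovery_on_brownian_data(self):
        tree = kt.simulate_yule_tree(60, seed=13)
        slopes = []
        for s in range(30):
            x = kt.simulate_brownian(tree, 1.0, seed=100 + s)
            noise = kt.simulate_brownian(tree, 0.5, seed=900 + s)
            y = 0.871 * x + noise
            slopes.append(kt.pgls(y, x, tree).slope)
        assert abs(np.mean(slopes) - 0.871) < 0.12
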