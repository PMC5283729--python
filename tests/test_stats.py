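import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from metabolokit.core_data import Dataset
from metabolokit.stats import (
    DesignSpec,
    PowerSpec,
    StatsError,
    adjust_bh,
    bootstrap_pvalue,
    factorial_test,
    multi_group_test,
    post_hoc,
    power_analysis,
    repeated_test,
    suggest_methods,
    two_group_test,
)
from metabolokit.stats import test_features as run_feature_tests


class TestSuggestMethods:
    def test_two_independent_row(self):
        s = suggest_methods("two_independent")
        assert [m["label"] for m in s["methods"]] == [
            "Welch's t test",
            "Mann-Whitney U test",
            "t test",
        ]
        assert s["default"] == "welch"

    def test_multi_independent_follow_up_names_games_howell_and_dunn(self):
        s = suggest_methods("multi_independent")
        assert s["default"] == "welch_anova"
        joined = " ".join(s["following"])
        assert "Games-Howell" in joined and "Dunn" in joined and "Bonferroni" in joined

    def test_multi_paired_names_greenhouse_geisser(self):
        s = suggest_methods("multi_paired")
        joined = " ".join(s["following"])
        assert "Greenhouse-Geisser" in joined and "Wilcoxon" in joined

    def test_unknown_design_errors(self):
        with pytest.raises(StatsError):
            suggest_methods("three_way")


class TestTwoGroup:
    def test_identical_groups_null(self):
        r = two_group_test([1.0, 2, 3], [1.0, 2, 3], "welch")
        assert r.statistic == 0 and r.p == 1

    def test_welch_hand_values(self):
        # x=(1,2,3), y=(2,4,6): t = -2/sqrt(5/3), Welch-Satterthwaite df
        r = two_group_test([1, 2, 3], [2, 4, 6], "welch")
        assert r.statistic == pytest.approx(-2 / np.sqrt(5 / 3), abs=1e-6)
        assert r.df == pytest.approx(2.9412, abs=1e-3)

    def test_mannwhitney_exact_against_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n1, n2 = rng.integers(3, 5, size=2)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            r = two_group_test(x, y, "mannwhitney")
            # enumeration oracle over all group assignments of the pooled ranks
            us = []
            for comb in itertools.combinations(range(n1 + n2), n1):
                xx = pooled[list(comb)]
                ranks = sps.rankdata(pooled)
                u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
                us.append(u)
            us = np.array(us)
            u_obs = sps.mannwhitneyu(x, y, method="exact").statistic
            mean_u = n1 * n2 / 2
            p_exact = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-9)
            assert r.p == pytest.approx(p_exact, abs=1e-12)
            assert r.extra["mode"] == "exact"

    def test_mannwhitney_three_vs_three(self):
        r = two_group_test([1, 2, 3], [4, 5, 6], "mannwhitney")
        assert r.p == pytest.approx(0.1)

    def test_mannwhitney_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(0.5, 1, size=15)
        p1 = two_group_test(x, y, "mannwhitney").p
        p2 = two_group_test(np.exp(x), np.exp(y), "mannwhitney").p
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_welch_equals_student_statistic_for_equal_sizes(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=10), rng.normal(size=10)
        w = two_group_test(x, y, "welch")
        s = two_group_test(x, y, "student")
        assert w.statistic == pytest.approx(s.statistic, abs=1e-12)
        assert w.df <= s.df

    def test_paired_is_one_sample_on_differences(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r = two_group_test(x, y, "welch", paired=True)
        t, p = sps.ttest_1samp(y - x, 0.0)
        assert r.statistic == pytest.approx(t) and r.p == pytest.approx(p)

    def test_zero_variance_guards(self):
        r = two_group_test([2.0, 2.0], [2.0, 2.0], "welch")
        assert r.p == 1 and r.statistic == 0
        with pytest.warns(UserWarning):
            r = two_group_test([2.0, 2.0], [3.0, 3.0], "welch")
        assert r.p == 0


class TestMultiGroup:
    def test_identical_groups(self):
        g = [[1.0, 2, 3]] * 3
        r = multi_group_test(g, "anova")
        assert r.statistic == pytest.approx(0) and r.p == pytest.approx(1)

    def test_kruskal_hand_formula(self):
        # groups {1,2},{3,4},{5,6}: rank means 1.5/3.5/5.5, no ties
        groups = [[1, 2], [3, 4], [5, 6]]
        n, N = 2, 6
        h = 12 / (N * (N + 1)) * n * ((1.5 - 3.5) ** 2 + (3.5 - 3.5) ** 2 + (5.5 - 3.5) ** 2)
        r = multi_group_test(groups, "kruskal")
        assert r.statistic == pytest.approx(h)
        assert r.p == pytest.approx(sps.chi2.sf(h, 2))

    def test_welch_anova_approaches_anova_in_balanced_homoscedastic_limit(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=500) for _ in range(3)]
        w = multi_group_test(groups, "welch_anova")
        a = multi_group_test(groups, "anova")
        assert w.statistic == pytest.approx(a.statistic, rel=2e-2)

    def test_welch_anova_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(5)
        groups = [rng.normal(0, s, size=n) for s, n in [(1, 8), (2, 12), (3, 10)]]
        r = multi_group_test(groups, "welch_anova")
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat(["a", "b", "c"], [8, 12, 10]),
            }
        )
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert r.statistic == pytest.approx(float(ref["F"][0]), abs=1e-8)
        assert r.p == pytest.approx(float(ref["p_unc"][0]), abs=1e-8)

    def test_single_group_errors(self):
        with pytest.raises(StatsError):
            multi_group_test([[1.0, 2.0]])


class TestRepeated:
    def test_identical_condition_means(self):
        y = np.tile([[1.0], [2.0], [3.0]], (1, 3))
        r = repeated_test(y, "repeated_anova")
        assert r.statistic == pytest.approx(0) and r.p == pytest.approx(1)

    def test_two_conditions_epsilon_is_one(self):
        rng = np.random.default_rng(6)
        r = repeated_test(rng.normal(size=(8, 2)), "repeated_anova")
        assert r.extra["epsilon"] == 1.0

    def test_friedman_perfect_ranking(self):
        # 3 subjects x 3 conditions, ranks (1,2,3) per subject -> chi2 = 6
        y = np.array([[1.0, 2, 3], [2, 4, 6], [1, 5, 9]])
        r = repeated_test(y, "friedman")
        assert r.statistic == pytest.approx(6.0)

    def test_matches_pingouin_rm_anova(self):
        import pingouin as pg

        rng = np.random.default_rng(7)
        y = rng.normal(size=(12, 4)) + np.array([0, 0.3, 0.6, 0.1])
        r = repeated_test(y, "repeated_anova")
        long = pd.DataFrame(
            {
                "y": y.ravel(),
                "s": np.repeat(np.arange(12), 4),
                "c": np.tile([f"c{j}" for j in range(4)], 12),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="c", subject="s", correction=True)
        assert r.extra["epsilon"] == pytest.approx(float(ref["eps"][0]), abs=1e-6)
        assert r.extra["p_uncorrected"] == pytest.approx(float(ref["p_unc"][0]), abs=1e-8)

    def test_incomplete_blocks_error(self):
        y = np.array([[1.0, 2, 3], [2, np.nan, 6]])
        with pytest.raises(StatsError, match="subject"):
            repeated_test(y)


class TestFactorial:
    @staticmethod
    def _balanced(seed=8, inter=0.0, n=6):
        rng = np.random.default_rng(seed)
        rows = []
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                mu = {"a1": 0, "a2": 1}[a] + {"b1": 0, "b2": 2}[b]
                if a == "a2" and b == "b2":
                    mu += inter
                for _ in range(n):
                    rows.append({"A": a, "B": b, "y": mu + rng.normal()})
        return pd.DataFrame(rows)

    def test_equal_cell_means_give_zero_f(self):
        rows = [
            {"A": a, "B": b, "y": y}
            for a in ("a1", "a2")
            for b in ("b1", "b2")
            for y in (1.0, 2.0, 3.0)
        ]
        r = factorial_test(pd.DataFrame(rows), "y", ("A", "B"))
        assert np.allclose(r.extra["anova_table"]["F"][:3], 0, atol=1e-10)

    def test_additive_data_has_zero_interaction_ss(self):
        rows = [
            {"A": f"a{i}", "B": f"b{j}", "y": float(i + 10 * j) + k * 0.0}
            for i in range(2)
            for j in range(3)
            for k in range(4)
        ]
        r = factorial_test(pd.DataFrame(rows), "y", ("A", "B"))
        t = r.extra["anova_table"].set_index("effect")
        assert t.loc["A:B", "SS"] == pytest.approx(0, abs=1e-9)

    def test_balanced_2x2_matches_projection_oracle(self):
        data = self._balanced(inter=1.5)
        r = factorial_test(data, "y", ("A", "B"))
        # independent oracle: explicit orthogonal-contrast projections
        y = data["y"].to_numpy()
        sa = np.where(data["A"] == "a2", 1.0, -1.0)
        sb = np.where(data["B"] == "b2", 1.0, -1.0)
        sab = sa * sb
        n = len(y)
        ss = {k: (v @ y) ** 2 / n for k, v in {"A": sa, "B": sb, "A:B": sab}.items()}
        resid = y - y.mean() - sum((c @ y) / n * c for c in (sa, sb, sab))
        ms_err = (resid @ resid) / (n - 4)
        t = r.extra["anova_table"].set_index("effect")
        for eff in ("A", "B", "A:B"):
            assert t.loc[eff, "SS"] == pytest.approx(ss[eff], rel=1e-9)
            assert t.loc[eff, "F"] == pytest.approx(ss[eff] / ms_err, rel=1e-9)

    def test_significant_interaction_triggers_simple_effects(self):
        data = self._balanced(inter=6.0, n=10)
        r = factorial_test(data, "y", ("A", "B"))
        assert r.post_hoc is not None
        assert set(r.post_hoc["within_level"]) == {"b1", "b2"}
        assert "p_adj" in r.post_hoc.columns

    def test_robust_trimming_resists_outliers(self):
        data = self._balanced(inter=0.0, n=10)
        data.loc[0, "y"] += 1000.0  # single gross outlier
        plain = factorial_test(data, "y", ("A", "B"), robust=False)
        robust = factorial_test(data, "y", ("A", "B"), robust=True)
        t_plain = plain.extra["anova_table"].set_index("effect")
        t_rob = robust.extra["anova_table"].set_index("effect")
        # outlier masks the B effect in the classical fit; trimming restores it
        assert t_rob.loc["B", "p"] < t_plain.loc["B", "p"]

    def test_empty_cell_errors(self):
        data = self._balanced()
        data = data[~((data["A"] == "a2") & (data["B"] == "b2"))]
        with pytest.raises(StatsError):
            factorial_test(data, "y", ("A", "B"))


class TestPostHoc:
    def test_identical_groups_all_adjusted_p_one(self):
        g = [[1.0, 2, 3, 4]] * 3
        for method in ("games_howell", "tukey", "dunn_bonferroni", "pairwise_bonferroni"):
            t = post_hoc(g, method=method)
            assert (t["p_adj"] >= 0.999).all(), method

    def test_dunn_hand_z(self):
        # {1,2},{3,4},{5,6}: pair (g1,g3) z = 4/sqrt(3.5)
        t = post_hoc([[1, 2], [3, 4], [5, 6]], method="dunn_bonferroni")
        pair = t[(t["group1"] == "g1") & (t["group2"] == "g3")]
        assert abs(pair["statistic"].iloc[0]) == pytest.approx(4 / np.sqrt(3.5), abs=1e-6)

    def test_games_howell_close_to_tukey_when_homoscedastic(self):
        rng = np.random.default_rng(9)
        g = [rng.normal(loc=m, size=50) for m in (0, 0.3, 0.6)]
        gh = post_hoc(g, method="games_howell").sort_values(["group1", "group2"])
        tk = post_hoc(g, method="tukey").sort_values(["group1", "group2"])
        assert np.allclose(gh["p_adj"].to_numpy(), tk["p_adj"].to_numpy(), atol=0.01)

    def test_two_groups_rejected(self):
        with pytest.raises(StatsError):
            post_hoc([[1, 2], [3, 4]], method="dunn_bonferroni")


class TestAdjustBH:
    def test_step_up_hand_example(self):
        out = adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_single_p_unchanged(self):
        assert adjust_bh([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            adjust_bh([0.5, 1.5])

    @given(
        p=st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None)
    def test_properties(self, p):
        p = np.asarray(p)
        out = adjust_bh(p)
        assert ((out >= 0) & (out <= 1)).all()
        bonf = np.minimum(p * len(p), 1)
        assert (out <= bonf + 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(out[order]) >= -1e-12).all()  # monotone in p rank
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(adjust_bh(p[perm]), out[perm])


class TestBootstrap:
    def test_seed_determinism(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert bootstrap_pvalue(x, y, B=200, seed=4) == bootstrap_pvalue(x, y, B=200, seed=4)

    def test_null_p_near_one_for_identical_pooled(self):
        x = np.arange(10.0)
        p = bootstrap_pvalue(x, x, B=500, seed=1)
        assert p > 0.5  # mean difference 0 is the modal resample outcome

    def test_small_b_rejected(self):
        with pytest.raises(StatsError):
            bootstrap_pvalue([1, 2, 3], [4, 5, 6], B=10)


class TestPower:
    def test_null_effect_posthoc_power_is_alpha(self):
        p = power_analysis(PowerSpec("post_hoc", "two_sample_t", 0.0, 0.05, n=20))
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_a_priori_two_sample_n17(self):
        n = power_analysis(PowerSpec("a_priori", "two_sample_t", 1.0, 0.05, power=0.8))
        assert n == 17

    def test_power_monotone_in_n(self):
        powers = [
            power_analysis(PowerSpec("post_hoc", "two_sample_t", 0.5, 0.05, n=n))
            for n in (10, 20, 40, 80)
        ]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_a_priori_then_post_hoc_meets_target(self):
        for d in (0.5, 0.8, 1.2):
            n = power_analysis(PowerSpec("a_priori", "two_sample_t", d, 0.05, power=0.8))
            achieved = power_analysis(PowerSpec("post_hoc", "two_sample_t", d, 0.05, n=n))
            assert achieved >= 0.8

    def test_zero_effect_a_priori_rejected(self):
        with pytest.raises(StatsError):
            power_analysis(PowerSpec("a_priori", "two_sample_t", 0.0, 0.05, power=0.8))


class TestTestFeatures:
    @staticmethod
    def _dataset(n_features=20, n=8, seed=0, paired=False):
        rng = np.random.default_rng(seed)
        cols = [f"S{i}" for i in range(2 * n)]
        mat = pd.DataFrame(
            rng.normal(10, 1, size=(n_features, 2 * n)),
            index=[f"F{i}" for i in range(n_features)],
            columns=cols,
        )
        meta = pd.DataFrame(
            {
                "group": ["a"] * n + ["b"] * n,
                "subject": [f"s{i % n}" for i in range(2 * n)],
            },
            index=cols,
        )
        return Dataset(mat, meta)

    def test_single_feature_pfdr_equals_p(self):
        d = self._dataset(n_features=1)
        res = run_feature_tests(d, DesignSpec("two_independent", ("group",)))
        assert res["pFDR"].iloc[0] == pytest.approx(res["p"].iloc[0])

    def test_paired_design_equals_one_sample_on_differences(self):
        d = self._dataset(n_features=5, seed=1)
        res = run_feature_tests(d, DesignSpec("two_paired", ("group",)))
        x = d.intensities.iloc[:, :8].to_numpy()
        y = d.intensities.iloc[:, 8:].to_numpy()
        t, p = sps.ttest_1samp(y - x, 0.0, axis=1)
        assert np.allclose(res["statistic"], t) and np.allclose(res["p"], p)

    def test_sparse_feature_flagged_not_dropped(self):
        d = self._dataset(n_features=3, n=4, seed=2)
        d.intensities.iloc[0, :7] = np.nan  # one group left with <2 values
        res = run_feature_tests(d, DesignSpec("two_independent", ("group",)))
        assert len(res) == 3
        assert res["p"].isna().iloc[0] and "note" in res.columns

    def test_multi_group_attaches_post_hoc(self):
        rng = np.random.default_rng(3)
        cols = [f"S{i}" for i in range(18)]
        mat = pd.DataFrame(
            rng.normal(size=(4, 18)), index=[f"F{i}" for i in range(4)], columns=cols
        )
        meta = pd.DataFrame({"group": np.repeat(["a", "b", "c"], 6)}, index=cols)
        res = run_feature_tests(Dataset(mat, meta), DesignSpec("multi_independent", ("group",)))
        ph = res.attrs["post_hoc"]
        assert set(ph["entity_id"]) == set(res["entity_id"])
        assert (ph.groupby("entity_id").size() == 3).all()  # 3 pairs of 3 groups
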