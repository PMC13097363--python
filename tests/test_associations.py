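import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hybridpanel.associations import (
    bh_adjust,
    bin_ploidy,
    compact_letter_display,
    compare_groups,
    fit_heterosis_model,
    grouped_correlation,
    label_cross_type,
)


def bh_oracle(p):
    """Step-up oracle: sort, scale by m/rank, enforce monotonicity."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBH:
    def test_matches_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 40)
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=100)
    def test_monotone_and_bounded(self, p):
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0) and np.all(adj >= np.asarray(p) - 1e-15)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestGroupedCorrelation:
    def test_perfect_line(self):
        df = pd.DataFrame({"g": ["a"] * 5, "x": [1, 2, 3, 4, 5]})
        df["y"] = 2 * df["x"] + 1
        out = grouped_correlation(df, ["g"], "x", "y")
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_constant_x_flagged_and_excluded_from_family(self):
        df = pd.DataFrame(
            {
                "g": ["a"] * 4 + ["b"] * 4,
                "x": [1.0] * 4 + [1, 2, 3, 4],
                "y": [1, 2, 3, 4] * 2,
            }
        )
        out = grouped_correlation(df, ["g"], "x", "y").set_index("g")
        assert out.loc["a", "note"] == "zero_variance"
        assert np.isnan(out.loc["a", "p_adj"])
        # family has a single member, so adjusted == raw
        assert out.loc["b", "p_adj"] == pytest.approx(out.loc["b", "p_raw"])

    def test_small_groups_flagged(self):
        df = pd.DataFrame({"g": ["a", "a"], "x": [1, 2], "y": [2, 1]})
        out = grouped_correlation(df, ["g"], "x", "y")
        assert out["note"].iloc[0] == "too_few"

    def test_bh_family_is_whole_grid(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "g": np.repeat(list("abcd"), 10),
                "x": rng.normal(size=40),
                "y": rng.normal(size=40),
            }
        )
        out = grouped_correlation(df, ["g"], "x", "y")
        np.testing.assert_allclose(
            out["p_adj"].to_numpy(), bh_oracle(out["p_raw"].tolist()), rtol=1e-12
        )


class TestCompareGroups:
    def test_null_groups_share_letter(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, 180)
        labels = np.repeat(["g1", "g2", "g3"], 60)
        res = compare_groups(values, labels, "anova_tukey")
        assert (res.pairwise["p_adj"] > 0.05).all()
        assert len(set(res.letters.values())) == 1

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(8)
        values = np.concatenate(
            [rng.normal(0, 1, 60), rng.normal(0, 1, 60), rng.normal(5, 1, 60)]
        )
        labels = np.repeat(["g1", "g2", "g3"], 60)
        res = compare_groups(values, labels, "anova_tukey")
        assert set(res.letters["g3"]).isdisjoint(set(res.letters["g1"]))
        assert res.letters["g1"] == res.letters["g2"]

    def test_anova_matches_statsmodels(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        values = np.array([1.1, 2.3, 1.9, 3.2, 2.8, 4.1, 3.9, 5.0, 4.4])
        labels = np.repeat(["a", "b", "c"], 3)
        res = compare_groups(values, labels, "anova_tukey")
        df = pd.DataFrame({"v": values, "g": labels})
        table = sm.stats.anova_lm(ols("v ~ C(g)", data=df).fit())
        assert res.p_value == pytest.approx(table["PR(>F)"].iloc[0], abs=1e-8)
        assert res.statistic == pytest.approx(table["F"].iloc[0], rel=1e-8)

    def test_tukey_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(9)
        values = np.concatenate([rng.normal(m, 1, 12) for m in (0, 0.8, 2.0)])
        labels = np.repeat(["a", "b", "c"], 12)
        res = compare_groups(values, labels, "anova_tukey")
        sm_res = pairwise_tukeyhsd(values, labels)
        ours = res.pairwise.set_index(["group_a", "group_b"])["p_adj"]
        for (ga, gb), p_sm in zip(
            itertools.combinations(["a", "b", "c"], 2), sm_res.pvalues
        ):
            assert ours[(ga, gb)] == pytest.approx(p_sm, abs=1e-6)

    def test_wilcoxon_matches_exact_enumeration(self):
        x = np.array([1.2, 3.4, 2.2, 5.1])
        y = np.array([0.4, 0.9, 2.8, 1.7, 0.2])
        res = compare_groups(
            np.concatenate([x, y]),
            np.array(["x"] * 4 + ["y"] * 5),
            "wilcoxon",
        )
        # enumerate every split of the pooled sample to get the exact U null
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        n1 = len(x)
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        us = []
        for idx in itertools.combinations(range(len(pooled)), n1):
            r = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            us.append(r)
        us = np.array(us)
        p_low = np.mean(us <= u_obs)
        p_high = np.mean(us >= u_obs)
        p_exact = min(1.0, 2 * min(p_low, p_high))
        assert res.p_value == pytest.approx(p_exact, abs=1e-8)

    def test_wilcoxon_needs_two_groups(self):
        with pytest.raises(ValueError):
            compare_groups([1, 2, 3], ["a", "a", "a"], "wilcoxon")

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], ["a", "a"], "anova_tukey")


class TestLetterDisplay:
    def test_no_differences_single_letter(self):
        letters = compact_letter_display(["a", "b", "c"], set())
        assert set(letters.values()) == {"a"}

    def test_consistent_with_pair_matrix(self):
        groups = ["g1", "g2", "g3", "g4"]
        sig = {("g1", "g4"), ("g2", "g4")}
        letters = compact_letter_display(groups, sig)
        for a, b in itertools.combinations(groups, 2):
            shares = bool(set(letters[a]) & set(letters[b]))
            assert shares != (tuple(sorted((a, b))) in sig)


class TestCrossType:
    def _meta(self, dom_a, dom_b):
        return pd.DataFrame(
            {
                "strain_id": ["W1", "W2", "A", "B", "H"],
                "role": ["wildtype", "wildtype", "mating_competent",
                         "mating_competent", "hybrid"],
                "parent_a": ["", "", "W1", "W2", "A"],
                "parent_b": ["", "", "", "", "B"],
                "domestication": [dom_a, dom_b, dom_a, dom_b, "NA"],
            }
        )

    def test_dd(self):
        lab = label_cross_type(self._meta("domesticated", "domesticated"))
        assert lab["H"] == "DD"

    def test_dw_symmetric(self):
        assert label_cross_type(self._meta("wild", "domesticated"))["H"] == "DW"
        assert label_cross_type(self._meta("domesticated", "wild"))["H"] == "DW"

    def test_ww(self):
        assert label_cross_type(self._meta("wild", "wild"))["H"] == "WW"

    def test_missing_label_is_na(self):
        assert pd.isna(label_cross_type(self._meta("NA", "wild"))["H"])

    def test_full_diallel_tally_matches_combinatorics(self):
        # 18 parents (12 domesticated, 6 wild), all unordered pairs
        doms = ["domesticated"] * 12 + ["wild"] * 6
        parents = [f"P{i}" for i in range(18)]
        rows = [
            {"strain_id": p, "role": "wildtype", "parent_a": "", "parent_b": "",
             "domestication": d}
            for p, d in zip(parents, doms)
        ]
        for i, (a, b) in enumerate(itertools.combinations(parents, 2)):
            rows.append(
                {"strain_id": f"H{i}", "role": "hybrid", "parent_a": a,
                 "parent_b": b, "domestication": "NA"}
            )
        labels = label_cross_type(pd.DataFrame(rows))
        counts = labels.value_counts()
        assert counts["DD"] == math.comb(12, 2)
        assert counts["WW"] == math.comb(6, 2)
        assert counts["DW"] == 12 * 6
        assert counts.sum() == math.comb(18, 2)


class TestRegression:
    def _records(self, n=60, seed=0, noise=0.0, cg=0.01, cp=-0.1):
        rng = np.random.default_rng(seed)
        g = rng.uniform(10, 500, n)
        p = rng.uniform(2, 8, n)
        y = cg * g + cp * p + (rng.normal(0, noise, n) if noise else 0.0)
        bph = np.expm1(y)  # so that log1p(bph) == y exactly
        return pd.DataFrame({"medium": "m1", "ibs_distance": g,
                             "ploidy_measured": p, "bph": bph})

    def test_noiseless_recovery(self):
        out = fit_heterosis_model(self._records()).iloc[0]
        assert out["coef_G"] == pytest.approx(0.01, rel=1e-9)
        assert out["coef_P"] == pytest.approx(-0.1, rel=1e-9)
        assert out["r_squared"] == pytest.approx(1.0, abs=1e-12)

    def test_standardized_beta_formula(self):
        rec = self._records(noise=0.3, seed=3)
        out = fit_heterosis_model(rec).iloc[0]
        y = np.log1p(rec["bph"])
        for col, b, bstd in [
            ("ibs_distance", out["coef_G"], out["beta_std_G"]),
            ("ploidy_measured", out["coef_P"], out["beta_std_P"]),
        ]:
            expected = b * rec[col].std(ddof=1) / y.std(ddof=1)
            assert bstd == pytest.approx(expected, rel=1e-12)

    def test_beta_invariant_under_predictor_rescaling(self):
        rec = self._records(noise=0.3, seed=4)
        out1 = fit_heterosis_model(rec).iloc[0]
        rec2 = rec.assign(ibs_distance=rec["ibs_distance"] * 37.5)
        out2 = fit_heterosis_model(rec2).iloc[0]
        assert out1["beta_std_G"] == pytest.approx(out2["beta_std_G"], rel=1e-9)
        assert out1["beta_std_P"] == pytest.approx(out2["beta_std_P"], rel=1e-9)

    def test_log1p_sign_preservation(self):
        rec = self._records(noise=0.5, seed=5)
        y = np.log1p(rec["bph"])
        assert np.all(np.sign(y) == np.sign(rec["bph"]))

    def test_bph_floor_applied(self):
        rec = self._records(n=20, seed=6)
        rec.loc[rec.index[0], "bph"] = -1.0
        out = fit_heterosis_model(rec).iloc[0]
        assert out["n_floored"] == 1

    def test_collinear_predictors_rejected(self):
        rec = self._records(n=20, seed=7)
        rec["ploidy_measured"] = rec["ibs_distance"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            fit_heterosis_model(rec)

    def test_matches_statsmodels_no_intercept(self):
        import statsmodels.api as sm

        rec = self._records(noise=0.4, seed=8)
        out = fit_heterosis_model(rec).iloc[0]
        y = np.log1p(rec["bph"])
        X = rec[["ibs_distance", "ploidy_measured"]]
        fit = sm.OLS(y, X).fit()
        assert out["coef_G"] == pytest.approx(fit.params["ibs_distance"], rel=1e-10)
        assert out["p_G"] == pytest.approx(fit.pvalues["ibs_distance"], abs=1e-10)
        assert out["r_squared"] == pytest.approx(fit.rsquared, rel=1e-10)


class TestBinPloidy:
    def test_high_ploidy_top_bin(self):
        assert bin_ploidy([4.6]).iloc[0] == ">4.5"

    def test_edge_goes_to_lower_bin(self):
        assert bin_ploidy([4.5]).iloc[0] == "(3.5,4.5]"
        assert bin_ploidy([2.5]).iloc[0] == "<=2.5"

    def test_counts_match_histogram_oracle(self):
        rng = np.random.default_rng(10)
        vals = rng.uniform(1.5, 8.5, 500)
        bins = bin_ploidy(vals)
        edges = [-np.inf, 2.5, 3.5, 4.5, np.inf]
        hist = np.histogram(np.nextafter(vals, -np.inf), bins=edges)[0]
        counts = bins.value_counts()
        labels = ["<=2.5", "(2.5,3.5]", "(3.5,4.5]", ">4.5"]
        np.testing.assert_array_equal([counts[l] for l in labels], hist)

    def test_non_monotone_edges(self):
        with pytest.raises(ValueError, match="increasing"):
            bin_ploidy([2.0], edges=(3.5, 2.5))
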