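"""Pearson screen, ANOVA post-hoc letters, and candidate bookkeeping."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from echotex.stats import (
    anova_oneway_tukey,
    anova_twoway_lsd,
    compact_letter_display,
    correlation_screen,
    count_candidates,
    evaluate_regression,
    format_regression_equation,
    pearson_with_regression,
    screen_percentage,
    strength_label,
)
from echotex.synthetic import TraitModel, simulate_trait_table


class TestPearson:
    def test_exact_linear_dependence(self):
        res = pearson_with_regression([1, 2, 3], [2, 4, 6])
        assert (res.r, res.slope, res.intercept) == (1.0, 2.0, 0.0)
        assert res.p == 0.0

    def test_hand_computed_example(self):
        # sxy = 3, sxx = 5, syy = 5 -> r = 0.6, slope = 0.6, intercept = 1.0
        res = pearson_with_regression([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6, abs=1e-12)
        assert res.slope == pytest.approx(0.6, abs=1e-12)
        assert res.intercept == pytest.approx(1.0, abs=1e-12)

    def test_p_is_one_when_r_zero(self):
        res = pearson_with_regression([1, 2, 3], [1, 0, 1])
        assert res.r == 0.0
        assert res.p == 1.0

    @pytest.mark.parametrize("x,y,msg", [
        ([1, 1, 1], [1, 2, 3], "zero variance"),
        ([1, 2, 3], [5, 5, 5], "zero variance"),
        ([1, 2], [3, 4], "n >= 3"),
        ([1, 2, 3], [1, 2], "equal-length"),
    ])
    def test_degenerate_inputs_rejected(self, x, y, msg):
        with pytest.raises(ValueError, match=msg):
            pearson_with_regression(x, y)

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(5, 40))
    def test_matches_scipy_and_passes_through_means(self, seed, n):
        """Independent cross-check against scipy plus the through-means invariant."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        res = pearson_with_regression(x, y)
        r_sp, p_sp = sps.pearsonr(x, y)
        lr = sps.linregress(x, y)
        assert res.r == pytest.approx(r_sp, abs=1e-12)
        assert res.p == pytest.approx(p_sp, rel=1e-9)
        assert res.slope == pytest.approx(lr.slope, abs=1e-12)
        assert res.intercept == pytest.approx(lr.intercept, abs=1e-12)
        assert np.mean(y) == pytest.approx(res.intercept + res.slope * np.mean(x),
                                           abs=1e-9)

    def test_null_p_values_are_uniform(self):
        """KS check on 10^4 independent null p-values (alpha = 0.001)."""
        rng = np.random.default_rng(99)
        ps = np.empty(10_000)
        X = rng.normal(size=(10_000, 10))
        Y = rng.normal(size=(10_000, 10))
        for i in range(10_000):
            ps[i] = pearson_with_regression(X[i], Y[i]).p
        assert sps.kstest(ps, "uniform").pvalue > 0.001


class TestBookkeeping:
    @pytest.mark.parametrize("args,expected", [
        ((4, 2, 26, 3), 624),
        ((4, 2, 26, 1), 208),
        ((1, 1, 1, 1), 1),
    ])
    def test_candidate_counts(self, args, expected):
        assert count_candidates(*args) == expected

    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            count_candidates(4, 0, 26, 3)

    def test_percentages_round_to_one_decimal(self):
        assert screen_percentage(19, 624) == 3.0
        assert screen_percentage(12, 208) == 5.8
        assert screen_percentage(0, 208) == 0.0


class TestStrengthLabel:
    @pytest.mark.parametrize("r,label", [
        (0.0, "slight"), (-0.15, "slight"), (0.25, "low"), (-0.41, "moderate"),
        (-0.67, "moderate"), (0.75, "high"), (-0.95, "very high"), (1.0, "very high"),
    ])
    def test_default_bands(self, r, label):
        assert strength_label(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            strength_label(1.2)

    def test_configurable_edges(self):
        bands = ((0.35, "weak"), (0.7, "moderate"))
        assert strength_label(0.3, bands=bands, top_label="strong") == "weak"
        assert strength_label(0.8, bands=bands, top_label="strong") == "strong"


class TestEquationFormatting:
    @pytest.mark.parametrize("intercept,slope,text", [
        (34.54, -0.15, "y = 34.54 - 0.15x"),
        (66.24, 0.42, "y = 66.24 + 0.42x"),
        (4.14, 0.007, "y = 4.14 + 0.007x"),
        (0.56, -0.002, "y = 0.56 - 0.002x"),
        (-4.98, 0.21, "y = -4.98 + 0.21x"),
    ])
    def test_ascii_two_decimal_rendering(self, intercept, slope, text):
        assert format_regression_equation(intercept, slope) == text

    def test_evaluate_regression(self):
        assert evaluate_regression(34.54, -0.15, 42.0) == pytest.approx(28.24)


def _study(seed, n=15, planted=()):
    model = TraitModel(target_correlations=list(planted))
    return simulate_trait_table(model, n_per_group=n, seed=seed)


class TestCorrelationScreen:
    def test_empty_screen_is_valid(self):
        traits, echo = _study(11)
        res = correlation_screen(echo, traits, alpha=1e-12, pooled=True,
                                 n_traits_bookkeeping=26)
        assert res.within.significant == 0
        assert res.within.percentage == 0.0
        assert res.within.results.empty
        assert res.within.possible == 624
        assert res.pooled.possible == 208

    def test_planted_strong_effect_is_flagged(self):
        traits, echo = _study(12, planted=[("L-MPH", "Moisture (%)", 0.9)])
        res = correlation_screen(echo, traits, alpha=0.05, pooled=False)
        hits = res.within.results
        match = hits[(hits.input_variable == "L-MPH")
                     & (hits.output_variable == "Moisture (%)")]
        assert len(match) == 3  # recovered in every group at n = 15
        assert (match.r > 0.5).all()

    def test_result_rows_pass_through_group_means(self):
        traits, echo = _study(13, planted=[("O1-MPI", "Protein (%)", 0.8)])
        res = correlation_screen(echo, traits, alpha=0.05, pooled=True)
        for table in (res.within, res.pooled):
            for row in table.results.itertuples():
                sub_e = echo[echo.plane == row.input_variable.split("-")[0]]
                sub_t = traits
                if row.group != "POOLED":
                    sub_e = sub_e[sub_e.group == row.group]
                    sub_t = traits[traits.group == row.group]
                stat = "mpi" if row.input_variable.endswith("MPI") else "mph"
                x = sub_e.set_index("bird_id")[stat]
                y = sub_t.set_index("bird_id")[row.output_variable].loc[x.index]
                assert y.mean() == pytest.approx(
                    row.intercept + row.slope * x.mean(), abs=1e-9)
                assert row.equation == format_regression_equation(row.intercept,
                                                                  row.slope)

    def test_significant_never_exceeds_possible(self):
        traits, echo = _study(14)
        res = correlation_screen(echo, traits, alpha=0.5, pooled=True)
        assert res.within.significant <= res.within.possible
        assert res.pooled.significant <= res.pooled.possible

    def test_unmatched_birds_are_listed(self):
        traits, echo = _study(15, n=4)
        traits = traits[traits.bird_id != "C-01"]
        with pytest.raises(ValueError, match="C-01"):
            correlation_screen(echo, traits)

    def test_bad_alpha_rejected(self):
        traits, echo = _study(16, n=4)
        with pytest.raises(ValueError, match="alpha"):
            correlation_screen(echo, traits, alpha=1.0)

    def test_bh_annotation_column(self):
        traits, echo = _study(17, planted=[("L-MPH", "Moisture (%)", 0.9)])
        res = correlation_screen(echo, traits, alpha=0.05, bh_annotation=True)
        assert "p_bh" in res.within.results.columns
        assert (res.within.results.p_bh >= res.within.results.p_value - 1e-15).all()


class TestOneWayTukey:
    def test_identical_groups_share_letter(self):
        res = anova_oneway_tukey({"C": [5, 5, 5], "E1": [5, 5, 5], "E2": [5, 5, 5]})
        assert res.f["group"] == 0.0
        assert res.p["group"] == 1.0
        assert set(res.letters["group"].values()) == {"a"}

    def test_two_group_f_is_squared_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 9)
        res = anova_oneway_tukey({"a": a, "b": b})
        t, p = sps.ttest_ind(a, b)
        assert res.f["group"] == pytest.approx(t ** 2, rel=1e-9)
        assert res.p["group"] == pytest.approx(p, rel=1e-9)

    def test_matches_statsmodels_tukey(self, rng):
        """Independent oracle: statsmodels pairwise_tukeyhsd p-values."""
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        data = {g: rng.normal(m, 1.0, 10) for g, m in [("C", 0), ("E1", 1), ("E2", 3)]}
        res = anova_oneway_tukey(data)
        values = np.concatenate(list(data.values()))
        labels = np.repeat(list(data), [len(v) for v in data.values()])
        sm_res = pairwise_tukeyhsd(values, labels)
        mine = {frozenset((r.level_a, r.level_b)): r.p_value
                for r in res.pairwise.itertuples()}
        for row, p in zip(sm_res._results_table.data[1:], sm_res.pvalues):
            assert mine[frozenset((row[0], row[1]))] == pytest.approx(p, abs=1e-6)

    def test_letters_consistent_with_pairwise(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            data = {g: r.normal(m, 1, 8)
                    for g, m in [("a", 0), ("b", r.uniform(0, 3)), ("c", r.uniform(0, 3)),
                                 ("d", r.uniform(0, 3))]}
            res = anova_oneway_tukey(data)
            letters = res.letters["group"]
            for row in res.pairwise.itertuples():
                shared = set(letters[row.level_a]) & set(letters[row.level_b])
                if row.significant:
                    assert not shared
                else:
                    assert shared

    def test_group_size_validation(self):
        with pytest.raises(ValueError, match="n >= 2"):
            anova_oneway_tukey({"a": [1], "b": [1, 2]})
        with pytest.raises(ValueError, match="2 groups"):
            anova_oneway_tukey({"a": [1, 2]})


class TestTwoWayLsd:
    @staticmethod
    def _frame(rng, group_effects, plane_effects, n=5, noise=1.0):
        rows = []
        for g, ge in group_effects.items():
            for p, pe in plane_effects.items():
                for v in rng.normal(ge + pe, noise, n):
                    rows.append({"group": g, "plane": p, "value": v})
        return pd.DataFrame(rows)

    def test_all_equal_both_f_zero(self):
        df = pd.DataFrame({"group": list("aabb") * 2, "plane": list("xyxy") * 2,
                           "value": [3.0] * 8})
        res = anova_twoway_lsd(df)
        assert res.f == {"group": 0.0, "plane": 0.0}
        assert res.p == {"group": 1.0, "plane": 1.0}

    def test_single_plane_reduces_to_oneway(self, rng):
        df = self._frame(rng, {"a": 0, "b": 1.5, "c": 0.5}, {"L": 0.0})
        res = anova_twoway_lsd(df)
        samples = {g: sub["value"].to_numpy() for g, sub in df.groupby("group")}
        one = anova_oneway_tukey(samples)
        assert res.factors == ("group",)
        assert res.f["group"] == pytest.approx(one.f["group"], rel=1e-9)

    def test_matches_statsmodels_main_effects(self, rng):
        df = self._frame(rng, {"C": 0, "E1": 1, "E2": 2},
                         {"L": 0, "T": -1, "O1": 0.5, "O2": 1}, n=6)
        res = anova_twoway_lsd(df)
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        fit = smf.ols("value ~ C(group) + C(plane)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res.f["group"] == pytest.approx(tab.loc["C(group)", "F"], rel=1e-9)
        assert res.p["plane"] == pytest.approx(tab.loc["C(plane)", "PR(>F)"], rel=1e-9)

    def test_planted_plane_effect_detected_group_null(self, rng):
        df = self._frame(rng, {"C": 0, "E1": 0, "E2": 0},
                         {"L": 0, "T": -2, "O1": 1, "O2": 2}, n=8, noise=1.0)
        res = anova_twoway_lsd(df)
        assert res.p["plane"] < 0.05
        assert res.p["group"] > 0.01  # null main effect rarely tiny

    def test_empty_cell_named(self):
        df = pd.DataFrame({"group": ["a", "a", "b"], "plane": ["x", "y", "x"],
                           "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="empty cell.*b.*y"):
            anova_twoway_lsd(df)


def test_compact_letter_display_orders_by_mean():
    letters = compact_letter_display(
        ["lo", "mid", "hi"], {"lo": 1.0, "mid": 2.0, "hi": 3.0},
        {frozenset(("lo", "hi")): True, frozenset(("lo", "mid")): False,
         frozenset(("mid", "hi")): False},
    )
    assert letters["hi"] == "a"
    assert letters["lo"] == "b"
    assert set(letters["mid"]) == {"a", "b"}
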