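"""Cross-species transforms, standardized regressions and one-way ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pollennet import (
    apply_transforms,
    fit_multiple_regression,
    one_way_anova,
    pattern_group_comparison,
)


@pytest.fixture()
def species_table():
    return pd.DataFrame(
        {
            "symmetry": ["radial", "bilateral", "radial", "bilateral"],
            "flower_size": [488.5, 100.0, 1000.0, 10.0],
            "hp_proportion": [0.5, 0.0, 10.0, 2.0],
            "d_prime": [0.25, 0.16, 0.01, 0.49],
            "strength": [1.0, 4.0, 0.25, 2.25],
            "closeness": [0.04, 0.01, 0.09, 0.16],
        },
        index=["sp1", "sp2", "sp3", "sp4"],
    )


class TestTransforms:
    def test_standard_transforms(self, species_table):
        out = apply_transforms(species_table)
        assert out.loc["sp1", "log10_flower_size"] == pytest.approx(np.log10(488.5))
        assert out.loc["sp1", "symmetry_code"] == 2  # radial
        assert out.loc["sp2", "symmetry_code"] == 1  # bilateral
        assert out.loc["sp4", "sqrt_d_prime"] == pytest.approx(0.7)
        assert out.loc["sp2", "sqrt_strength"] == pytest.approx(2.0)

    def test_zero_hp_flagged_not_errored(self, species_table):
        out = apply_transforms(species_table)
        assert bool(out.loc["sp2", "zero_hp"])
        assert np.isnan(out.loc["sp2", "log10_hp_proportion"])
        assert out.loc["sp3", "log10_hp_proportion"] == pytest.approx(1.0)

    def test_negative_input_names_species(self, species_table):
        species_table.loc["sp3", "d_prime"] = -0.1
        with pytest.raises(ValueError, match="sp3"):
            apply_transforms(species_table)


class TestMultipleRegression:
    def test_perfect_single_predictor(self):
        df = pd.DataFrame({"y": [2, 4, 6, 8.0], "x": [1, 2, 3, 4.0]})
        res = fit_multiple_regression(df, "y", ["x"])
        assert res.terms.loc["x", "std_coef"] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal_predictors_equal_marginal_correlations(self):
        # hand-built 6-row design with exactly orthogonal centered predictors
        x1 = np.array([1, 1, 1, -1, -1, -1.0])
        x2 = np.array([1, -1, 0, 1, -1, 0.0])
        assert x1 @ x2 == 0
        y = 2.0 * x1 + 1.0 * x2 + np.array([0.1, -0.1, 0.0, 0.1, -0.1, 0.0])
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        res = fit_multiple_regression(df, "y", ["x1", "x2"])
        for x, name in ((x1, "x1"), (x2, "x2")):
            r = np.corrcoef(x, y)[0, 1]
            assert res.terms.loc[name, "std_coef"] == pytest.approx(r, abs=1e-9)

    def test_standardized_coef_affine_invariant(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.normal(size=12)})
        df["y"] = 3 * df["x"] + rng.normal(size=12)
        base = fit_multiple_regression(df, "y", ["x"]).terms.loc["x", "std_coef"]
        df["x"] = 100.0 * df["x"] + 7.0
        scaled = fit_multiple_regression(df, "y", ["x"]).terms.loc["x", "std_coef"]
        assert scaled == pytest.approx(base)

    def test_rank_deficiency_names_terms(self):
        df = pd.DataFrame(
            {"y": [1, 2, 3, 4, 5.0], "a": [1, 2, 3, 4, 5.0], "b": [2, 4, 6, 8, 10.0]}
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_multiple_regression(df, "y", ["a", "b"])

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"y": [1, 2, 3, 4.0], "c": [1, 1, 1, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            fit_multiple_regression(df, "y", ["c"])


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.fvalue == pytest.approx(0.0)
        assert res.df_between == 1 and res.df_within == 4

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 12)
        res = one_way_anova(np.concatenate([a, b]), ["a"] * 10 + ["b"] * 12)
        t, p = stats.ttest_ind(a, b)  # pooled-variance two-sample t
        assert res.fvalue == pytest.approx(t**2)
        assert res.pvalue == pytest.approx(p)

    def test_shift_and_relabel_invariance(self):
        vals = np.array([1.0, 4.0, 2.0, 6.0, 3.0, 5.0])
        labels = ["g1", "g1", "g2", "g2", "g3", "g3"]
        base = one_way_anova(vals, labels)
        shifted = one_way_anova(vals + 100.0, labels)
        relabeled = one_way_anova(vals, ["x" + l for l in labels])
        assert shifted.fvalue == pytest.approx(base.fvalue)
        assert relabeled.fvalue == pytest.approx(base.fvalue)

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            one_way_anova([1, 1, 2, 2], ["a", "a", "b", "b"])


class TestPatternGroupComparison:
    def test_group_means_and_single_group_warning(self):
        table = pd.DataFrame(
            {"mean_hp": [1.0, 2.0, 10.0, 12.0], "flower_size": [10.0, 100.0, 40.0, 90.0]},
            index=["a", "b", "c", "d"],
        )
        patterns = pd.Series(
            ["no_pattern", "no_pattern", "linear", "linear"], index=table.index
        )
        comparison, anovas = pattern_group_comparison(table, patterns)
        hp = comparison[comparison["variable"] == "mean_hp"].set_index("group")
        assert hp.loc["linear", "mean"] == pytest.approx(11.0)
        assert hp.loc["no_pattern", "mean"] == pytest.approx(1.5)
        assert "mean_hp" in anovas

        one_group = pd.Series(["linear"] * 4, index=table.index)
        with pytest.warns(UserWarning):
            comparison, anovas = pattern_group_comparison(table, one_group)
        assert anovas == {}
        assert comparison["F"].isna().all()

    def test_full_regression_stack_runs(self, small_community):
        # end-to-end: simulated 6-species table, all responses finite
        from pollennet import summarize_all_species, classify_all

        summaries = summarize_all_species(small_community.stigmas)
        traits = small_community.traits.set_index("species")
        table = apply_transforms(summaries.join(traits))
        table["x_size"] = table["log10_flower_size"]
        res = fit_multiple_regression(table, "mean_hp", ["x_size", "symmetry_code"])
        assert np.isfinite(res.r_squared)
        assert np.isfinite(res.terms["std_coef"]).all()
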