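"""CP-HP accrual classifier: exact fits, decision rule, and recovery on
seeded simulated regimes."""

import numpy as np
import pandas as pd
import pytest

from pollennet import (
    CPHPPatternModel,
    classify_all,
    classify_species,
    fit_exponential,
    fit_linear,
    pattern_tallies,
)
from pollennet.simulate import SimulationConfig, _stigma_counts_for_regime


def loads_df(species, cp, hp):
    return pd.DataFrame(
        {
            "stigma_id": [f"{species}_s{i}" for i in range(len(cp))],
            "species": species,
            "cp": cp,
            "hp": hp,
            "hp_diversity": [1 if h > 0 else 0 for h in hp],
        }
    )


class TestFitLinear:
    def test_exact_line(self):
        fit = fit_linear(np.array([1, 2, 3]), np.array([2, 4, 6]))
        assert fit.coef == pytest.approx(2.0)
        assert fit.adj_r_squared == pytest.approx(1.0)
        assert fit.pvalue < 1e-6

    def test_constant_hp_not_significant(self):
        fit = fit_linear(np.array([1, 2, 3, 4.0]), np.array([3, 3, 3, 3.0]))
        assert fit.coef == pytest.approx(0.0, abs=1e-12)
        assert fit.pvalue == pytest.approx(1.0)

    def test_constant_cp_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear(np.array([5, 5, 5]), np.array([1, 2, 3]))

    def test_recovers_seeded_slope_within_ci(self):
        rng = np.random.default_rng(7)
        cp = rng.uniform(0, 100, 50)
        hp = 0.1 * cp + rng.normal(0, 1, 50)
        fit = fit_linear(cp, hp)
        # closed-form OLS slope SE for the oracle interval
        xc = cp - cp.mean()
        resid = hp - (fit.intercept + fit.coef * cp)
        se = np.sqrt(resid @ resid / 48 / (xc @ xc))
        assert abs(fit.coef - 0.1) < 1.96 * se


class TestFitExponential:
    def test_exact_curve_recovered(self):
        cp = np.array([10, 50, 100, 150, 200.0])
        hp = np.exp(0.5 + 0.01 * cp)
        fit = fit_exponential(cp, hp)
        assert fit.intercept == pytest.approx(0.5, abs=1e-6)
        assert fit.coef == pytest.approx(0.01, abs=1e-8)
        assert fit.adj_r_squared == pytest.approx(1.0)

    def test_constant_hp_flat(self):
        fit = fit_exponential(np.array([1, 5, 9, 20.0]), np.array([3, 3, 3, 3.0]))
        assert fit.coef == pytest.approx(0.0, abs=1e-6)
        assert not fit.significant(0.05)

    def test_poisson_noise_sign_recovery(self):
        # positive rate recovered with significance in the vast majority of seeds
        hits = 0
        n_rep = 50
        for r in range(n_rep):
            rng = np.random.default_rng(1000 + r)
            cp = rng.uniform(0, 150, 50)
            hp = rng.poisson(np.exp(0.2 + 0.02 * cp))
            fit = fit_exponential(cp, hp)
            if fit.converged and fit.coef > 0 and fit.pvalue < 0.05:
                hits += 1
        assert hits >= int(0.9 * n_rep)


class TestClassifier:
    def test_zero_hp_species(self):
        res = classify_species(loads_df("A", [5, 10, 15, 20], [0, 0, 0, 0]))
        assert res.pattern == "no_hp"
        assert res.pattern_group == "no_pattern"
        assert res.chosen is None

    def test_independent_regime_no_pattern(self):
        rng = np.random.default_rng(3)
        cp = rng.poisson(100, 50)
        hp = rng.poisson(1, 50)
        res = CPHPPatternModel(cp, hp, species="sim").fit()
        assert res.pattern == "no_pattern"

    def test_exponential_regime_recovered(self):
        rng = np.random.default_rng(5)
        lam = rng.gamma(4, 25, 50)
        cp = rng.poisson(lam)
        hp = rng.poisson(np.exp(0.5 + 0.015 * lam))
        res = CPHPPatternModel(cp, hp).fit()
        assert res.pattern == "increasing_exponential"
        assert res.chosen.coef > 0

    def test_decreasing_exponential_sign(self):
        rng = np.random.default_rng(9)
        lam = rng.gamma(4, 25, 50)
        cp = rng.poisson(lam)
        hp = rng.poisson(np.exp(3.0 - 0.02 * lam))
        res = CPHPPatternModel(cp, hp).fit()
        assert res.pattern == "decreasing_exponential"

    def test_choice_by_adjusted_r2_is_deterministic(self):
        rng = np.random.default_rng(21)
        cfg = SimulationConfig()
        cp, hp = _stigma_counts_for_regime("tolerance_linear", 50, cfg, rng)
        first = CPHPPatternModel(cp, hp).fit()
        second = CPHPPatternModel(cp, hp).fit()
        assert first.pattern == second.pattern
        assert first.chosen.model == second.chosen.model
        if first.linear.significant(0.05) and first.exponential.significant(0.05):
            better = (
                "linear"
                if first.linear.adj_r_squared >= first.exponential.adj_r_squared
                else "exponential"
            )
            assert first.chosen.model == better

    def test_order_and_empty_stigma_invariance(self):
        rng = np.random.default_rng(17)
        cp = rng.poisson(50, 40)
        hp = rng.poisson(0.1 * cp)
        df = loads_df("A", cp.tolist() + [0, 0], hp.tolist() + [0, 0])
        base = classify_species(df)
        shuffled = classify_species(df.sample(frac=1, random_state=2))
        assert base.pattern == shuffled.pattern
        assert base.n_analyzed == 40  # empty stigmas dropped pre-fit

    def test_too_few_stigmas_rejected(self):
        with pytest.raises(ValueError, match="3"):
            classify_species(loads_df("A", [1, 2], [0, 1]))


class TestClassifyAll:
    def test_three_regime_toy_community(self):
        rng = np.random.default_rng(41)
        cfg = SimulationConfig()
        frames = []
        for sp, regime in [
            ("L1", "tolerance_linear"),
            ("E1", "tolerance_exp_increasing"),
            ("N1", "avoidance"),
        ]:
            cp, hp = _stigma_counts_for_regime(regime, 50, cfg, rng)
            frames.append(loads_df(sp, cp, hp))
        table = classify_all(pd.concat(frames, ignore_index=True))
        tallies = pattern_tallies(table)
        assert tallies["no_pattern"] == 1
        assert tallies["linear"] + tallies["exponential"] == 2
        assert table.loc["E1", "pattern"] == "increasing_exponential"

    def test_pure_cp_community_all_no_hp(self):
        df = pd.concat(
            [loads_df(sp, [5, 10, 15, 20], [0, 0, 0, 0]) for sp in ("A", "B")],
            ignore_index=True,
        )
        table = classify_all(df)
        assert (table["pattern"] == "no_hp").all()
        assert pattern_tallies(table) == {"linear": 0, "exponential": 0, "no_pattern": 2}

    def test_skips_sparse_species_with_warning(self):
        df = pd.concat(
            [loads_df("A", [1, 2], [0, 1]), loads_df("B", [1, 2, 3, 4], [0, 1, 0, 1])],
            ignore_index=True,
        )
        with pytest.warns(UserWarning, match="skipped"):
            table = classify_all(df)
        assert list(table.index) == ["B"]
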