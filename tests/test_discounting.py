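import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effortframe.discounting import (
    FAMILIES,
    ContrastResult,
    auc_table,
    choice_loglik,
    compare_models,
    compute_auc,
    fit_all_families,
    fit_model,
    gain_loss_contrast,
    subjective_value,
)
from effortframe.staircase import HIGH, LOW, ChoiceTrial
from effortframe.synthetic_data import AgentParams, generate_choice_dataset, trials_from_frame


class TestSubjectiveValue:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_k_zero_is_identity(self, family):
        p = 10.0 if family == "sigmoid" else None
        assert subjective_value(family, 7.3, 25.0, 0.0, p) == pytest.approx(7.3)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_zero_effort_returns_amount(self, family):
        p = 10.0 if family == "sigmoid" else None
        assert subjective_value(family, 10.0, 0.0, 0.05, p) == pytest.approx(10.0)

    def test_quadratic_forced_zero(self):
        assert subjective_value("quadratic", 10.0, 30.0, 1.0 / 900.0) == 0.0

    def test_hyperbolic_arithmetic(self):
        assert subjective_value("hyperbolic", 10.0, 5.0, 0.2) == pytest.approx(5.0)

    def test_exponential_arithmetic(self):
        assert subjective_value("exponential", 10.0, 10.0, 0.1) == pytest.approx(
            10.0 * math.exp(-1.0)
        )

    def test_linear_clipped_at_zero(self):
        assert subjective_value("linear", 10.0, 30.0, 0.1) == 0.0

    def test_sigmoid_requires_inflection(self):
        with pytest.raises(ValueError):
            subjective_value("sigmoid", 10.0, 5.0, 0.5)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            subjective_value("cubic", 10.0, 5.0, 0.5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            subjective_value("linear", -1.0, 5.0, 0.1)
        with pytest.raises(ValueError):
            subjective_value("linear", 1.0, 5.0, -0.1)

    @pytest.mark.parametrize("family", FAMILIES)
    @given(k=st.floats(min_value=1e-4, max_value=0.5))
    @settings(max_examples=25, deadline=None)
    def test_non_increasing_in_effort(self, family, k):
        p = 10.0 if family == "sigmoid" else None
        efforts = np.linspace(0, 30, 61)
        sv = subjective_value(family, 10.0, efforts, k, p)
        assert np.all(np.diff(sv) <= 1e-12)
        assert sv[0] == pytest.approx(10.0)


class TestChoiceLoglik:
    def test_tied_values_give_log_half(self):
        t = ChoiceTrial(1, 30, 10.0, 10.0)  # k=0: SVs equal
        ll = choice_loglik([t], [HIGH], "linear", k=0.0, beta=1.0)
        assert ll == pytest.approx(math.log(0.5))

    def test_logistic_example(self):
        # k=0 so dSV = amount_high - amount_low = ln 3 -> P(high) = 0.75
        t = ChoiceTrial(1, 30, 10.0 - math.log(3.0), 10.0)
        ll = choice_loglik([t], [HIGH], "linear", k=0.0, beta=1.0)
        assert ll == pytest.approx(math.log(0.75), abs=1e-12)

    def test_large_beta_consistent_choices_approach_zero(self):
        t = ChoiceTrial(1, 30, 4.0, 10.0)
        ll = choice_loglik([t], [HIGH], "linear", k=0.0, beta=50.0)
        assert -1e-6 < ll <= 0.0

    def test_empty_trials_error(self):
        with pytest.raises(ValueError):
            choice_loglik([], [], "linear", k=0.0, beta=1.0)

    def test_loglik_nonpositive(self):
        trials = [ChoiceTrial(1, 30, a, 10.0) for a in (2.0, 5.0, 8.0)]
        ll = choice_loglik(trials, [HIGH, LOW, LOW], "quadratic", k=0.001, beta=2.0)
        assert ll <= 0.0


def _simulate_trials(agent, n_levels=(5.0, 10.0, 20.0, 30.0), seed=0):
    choices_df, _ = generate_choice_dataset([agent], n_levels, seed=seed,
                                            frames=("gain",))
    return trials_from_frame(choices_df)


class TestFitModel:
    def test_quadratic_recovery_example(self):
        agent = AgentParams("s01", "quadratic", 0.002, 0.002, beta=10.0, rng_seed=7)
        trials, ch = _simulate_trials(agent)
        fit = fit_model(trials, ch, "quadratic")
        assert fit.n_trials == 40
        assert abs(fit.k - 0.002) / 0.002 < 0.25

    def test_null_agent_recovers_zero_k(self):
        agent = AgentParams("s01", "quadratic", 0.0, 0.0, beta=10.0, rng_seed=3)
        trials, ch = _simulate_trials(agent)
        fit = fit_model(trials, ch, "quadratic")
        assert fit.k <= 1e-4

    def test_mle_dominates_generating_parameters(self):
        agent = AgentParams("s01", "quadratic", 0.002, 0.002, beta=10.0, rng_seed=11)
        trials, ch = _simulate_trials(agent, seed=5)
        fit = fit_model(trials, ch, "quadratic")
        gen_ll = choice_loglik(trials, ch, "quadratic", k=0.002, beta=10.0)
        assert fit.loglik >= gen_ll - 1e-9

    def test_bic_identity(self):
        agent = AgentParams("s01", "quadratic", 0.002, 0.002, beta=10.0, rng_seed=1)
        trials, ch = _simulate_trials(agent)
        fit = fit_model(trials, ch, "quadratic")
        assert fit.bic == pytest.approx(
            fit.n_params * math.log(fit.n_trials) - 2 * fit.loglik
        )

    def test_too_few_trials_error(self):
        t = ChoiceTrial(1, 30, 5.0, 10.0)
        with pytest.raises(ValueError):
            fit_model([t, t], [HIGH, LOW], "quadratic")


class TestCompareModels:
    def test_bic_arithmetic(self):
        # n=40, 2 params, loglik=-20 -> BIC = 2 ln 40 + 40
        assert 2 * math.log(40) + 40 == pytest.approx(47.37774, abs=1e-4)

    def test_fewer_params_win_ties(self):
        from effortframe.discounting import DiscountFit

        fits = []
        for fam in FAMILIES:
            npar = 3 if fam == "sigmoid" else 2
            fits.append(
                DiscountFit(
                    subject_id="s01", frame="gain", family=fam, k=0.01,
                    beta=1.0, loglik=-20.0, n_trials=40,
                    bic=npar * math.log(40) + 40.0,
                )
            )
        comp = compare_models(fits)
        # equal logliks: every 2-param family has equal BIC; tie breaks to
        # the fixed family order -> hyperbolic
        assert comp.per_subject["winner"].iloc[0] == "hyperbolic"

    def test_winner_has_minimal_bic(self):
        agent = AgentParams("s01", "quadratic", 0.003, 0.003, beta=10.0, rng_seed=2)
        trials, ch = _simulate_trials(agent)
        fits = fit_all_families(trials, ch)
        comp = compare_models(fits)
        winner_bic = comp.per_subject.query("family == winner")["bic"].iloc[0]
        assert winner_bic == pytest.approx(comp.per_subject["bic"].min())

    def test_mismatched_trial_counts_rejected(self):
        from effortframe.discounting import DiscountFit

        fits = [
            DiscountFit("s01", "gain", fam, 0.01, 1.0, -20.0,
                        40 if fam != "linear" else 39, 47.4)
            for fam in FAMILIES
        ]
        with pytest.raises(ValueError):
            compare_models(fits)

    def test_missing_family_rejected(self):
        from effortframe.discounting import DiscountFit

        fits = [DiscountFit("s01", "gain", "linear", 0.01, 1.0, -20.0, 40, 47.4)]
        with pytest.raises(ValueError):
            compare_models(fits)


class TestComputeAUC:
    def test_no_discounting_gives_one(self):
        assert compute_auc([5, 10, 20, 30], [10, 10, 10, 10]) == pytest.approx(1.0)

    def test_linear_decline_to_zero_gives_half(self):
        levels = np.array([5.0, 10.0, 20.0, 30.0])
        x = np.concatenate([[1.0], levels]) / 30.0
        y = 1.0 - (x - x[0]) / (x[-1] - x[0])  # linear from 1 at x_first to 0
        assert compute_auc(levels, 10.0 * y[1:]) == pytest.approx(0.5)

    def test_frozen_oracle_value(self):
        # y = {1, .8, .6, .4, .2} at {1, 5, 10, 20, 30} min; trapezoid area
        # = 15.1/30 over x-range 29/30 (verified by fine-grid quadrature)
        auc = compute_auc([5, 10, 20, 30], [8.0, 6.0, 4.0, 2.0])
        assert auc == pytest.approx(15.1 / 29.0, abs=1e-12)

    def test_quadrature_oracle(self, rng):
        levels = np.array([5.0, 10.0, 20.0, 30.0])
        for _ in range(25):
            vals = np.sort(rng.uniform(0, 10, 4))[::-1]
            auc = compute_auc(levels, vals)
            x = np.concatenate([[1.0], levels]) / 30.0
            y = np.concatenate([[1.0], vals / 10.0])
            grid = np.linspace(x[0], x[-1], 100_001)
            oracle = np.trapezoid(np.interp(grid, x, y), grid) / (x[-1] - x[0])
            assert auc == pytest.approx(oracle, abs=1e-9)

    def test_missing_level_error(self):
        with pytest.raises(ValueError):
            compute_auc([5, 10, 20, 30], [8.0, np.nan, 4.0, 2.0])

    def test_out_of_range_value_error(self):
        with pytest.raises(ValueError):
            compute_auc([5, 10, 20, 30], [8.0, 6.0, 4.0, 11.0])

    @given(
        scale_m=st.floats(min_value=0.1, max_value=10.0),
        scale_e=st.floats(min_value=0.1, max_value=10.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_rescaling(self, scale_m, scale_e):
        levels = np.array([5.0, 10.0, 20.0, 30.0])
        vals = np.array([8.0, 6.0, 3.0, 1.0])
        base = compute_auc(levels, vals)
        scaled = compute_auc(
            levels * scale_e,
            vals * scale_m,
            amount_high=10.0 * scale_m,
            reference_level=1.0 * scale_e,
        )
        assert scaled == pytest.approx(base, abs=1e-12)


class TestGainLossContrast:
    def test_identical_values_give_t_zero(self):
        r = gain_loss_contrast([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert r.t == 0.0 and np.all(r.differences == 0.0)

    def test_constant_nonzero_difference_flagged(self):
        r = gain_loss_contrast([0.1, 0.2, 0.3], [1.1, 1.2, 1.3])
        assert r.degenerate and math.isinf(r.t) and r.t > 0

    def test_sqrt_transform(self):
        g, l = [4.0, 9.0, 16.0], [1.0, 4.0, 9.0]
        r = gain_loss_contrast(g, l, transform="sqrt")
        assert np.allclose(r.differences, np.sqrt(l) - np.sqrt(g))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            gain_loss_contrast([1.0, 2.0], [2.0, 3.0])

    def test_matches_scipy(self, rng):
        from scipy import stats

        g = rng.normal(0.5, 0.1, 20)
        l = g + rng.normal(0.05, 0.05, 20)
        r = gain_loss_contrast(g, l)
        ref = stats.ttest_rel(l, g)
        assert r.t == pytest.approx(ref.statistic)
        assert r.p == pytest.approx(ref.pvalue)
        assert r.df == 19


def test_auc_table_round_trip():
    import pandas as pd

    indiff = pd.DataFrame(
        dict(
            subject=["a"] * 4 + ["a"] * 4,
            frame=["gain"] * 4 + ["loss"] * 4,
            effort_level=[5, 10, 20, 30] * 2,
            indifference=[8, 6, 4, 2, 9, 7, 5, 3],
        )
    )
    table = auc_table(indiff)
    assert set(table["frame"]) == {"gain", "loss"}
    gain_auc = table.query("frame == 'gain'")["auc"].iloc[0]
    assert gain_auc == pytest.approx(15.1 / 29.0)
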