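"""Likelihood, multi-start optimisation, and AIC/BIC model comparison."""

import math

import numpy as np
import pandas as pd
import pytest

from effortdisc import (
    DiscountModelSpec,
    FitResult,
    SharingClass,
    compare_models,
    difficulty_index,
    fit_all_models,
    fit_model,
    negative_log_likelihood,
)
from effortdisc.fitting import BETA_BOUNDS, K_BOUNDS


def _trials(rows):
    return pd.DataFrame(rows, columns=["subject", "domain", "effort_level", "reward", "choice"])


# 10-trial fixture for the hand-computed likelihood oracle
FIXTURE_TRIALS = [
    ("s0", "cognitive", 2, 2, "offer"),
    ("s0", "cognitive", 3, 10, "offer"),
    ("s0", "cognitive", 4, 4, "baseline"),
    ("s0", "cognitive", 5, 8, "offer"),
    ("s0", "cognitive", 6, 2, "baseline"),
    ("s0", "physical", 2, 6, "offer"),
    ("s0", "physical", 3, 2, "baseline"),
    ("s0", "physical", 4, 10, "offer"),
    ("s0", "physical", 5, 4, "baseline"),
    ("s0", "physical", 6, 6, "offer"),
]


def _oracle_nll(trials, k, beta):
    """Per-trial spreadsheet-style computation with plain math, hyperbolic SV."""
    total = 0.0
    for _, _, level, reward, choice in trials:
        E = (level - 1) / 5
        sv = reward / (1 + k * E)
        p_offer = math.exp(beta * sv) / (math.exp(beta * 1) + math.exp(beta * sv))
        total -= math.log(p_offer if choice == "offer" else 1 - p_offer)
    return total


class TestNegativeLogLikelihood:
    def test_equal_value_trial_costs_ln2(self, shared_hyperbolic):
        # hyperbolic SV(R=2, E=1, k=1) = 1 = baseline, so p = 0.5 at any beta
        data = _trials([("s0", "cognitive", 6, 2, "offer")])
        for beta in (0.5, 3.0, 20.0):
            nll = negative_log_likelihood([1.0, beta], data, shared_hyperbolic)
            assert nll == pytest.approx(math.log(2), abs=1e-12)

    def test_additive_over_trials(self, shared_hyperbolic):
        data = _trials(
            [("s0", "cognitive", 6, 2, "offer"), ("s0", "physical", 6, 2, "baseline")]
        )
        nll = negative_log_likelihood([1.0, 4.0], data, shared_hyperbolic)
        assert nll == pytest.approx(2 * math.log(2), abs=1e-12)

    def test_matches_hand_computed_oracle(self, shared_hyperbolic):
        nll = negative_log_likelihood(
            [0.5, 3.0], _trials(FIXTURE_TRIALS), shared_hyperbolic
        )
        assert nll == pytest.approx(_oracle_nll(FIXTURE_TRIALS, 0.5, 3.0), abs=1e-10)

    def test_missing_trials_excluded(self, shared_hyperbolic):
        data = _trials(
            [("s0", "cognitive", 6, 2, "offer"), ("s0", "physical", 3, 8, "missing")]
        )
        nll = negative_log_likelihood([1.0, 2.0], data, shared_hyperbolic)
        assert nll == pytest.approx(math.log(2), abs=1e-12)

    def test_all_missing_rejected(self, shared_hyperbolic):
        with pytest.raises(ValueError, match="non-missing"):
            negative_log_likelihood(
                [1.0, 2.0], _trials([("s0", "cognitive", 2, 2, "missing")]), shared_hyperbolic
            )

    def test_out_of_bounds_params_infeasible(self, shared_hyperbolic):
        data = _trials(FIXTURE_TRIALS)
        assert negative_log_likelihood([-0.1, 2.0], data, shared_hyperbolic) == np.inf
        assert negative_log_likelihood([1.0, 200.0], data, shared_hyperbolic) == np.inf

    def test_nll_nonnegative(self, sim_choices, winning_spec):
        nll = negative_log_likelihood([1.0, 2.0, 5.0, 5.0], sim_choices, winning_spec)
        assert nll >= 0


class TestFitModel:
    def test_optimizer_beats_grid_search(self, sim_choices, shared_hyperbolic):
        """On a 2-parameter model the multi-start NLL must be <= a dense grid."""
        fit = fit_model(sim_choices, shared_hyperbolic, n_restarts=10, seed=5)
        ks = np.linspace(K_BOUNDS[0], K_BOUNDS[1], 200)
        betas = np.linspace(BETA_BOUNDS[0], BETA_BOUNDS[1], 200)
        grid_min = min(
            negative_log_likelihood([k, b], sim_choices, shared_hyperbolic)
            for k in ks
            for b in betas
        )
        assert fit.neg_log_lik <= grid_min + 1e-6

    def test_refit_same_seed_is_bitwise_identical(self, sim_choices, winning_spec):
        a = fit_model(sim_choices, winning_spec, n_restarts=5, seed=9)
        b = fit_model(sim_choices, winning_spec, n_restarts=5, seed=9)
        assert a.params == b.params and a.neg_log_lik == b.neg_log_lik

    def test_more_restarts_never_worse(self, sim_choices, shared_hyperbolic):
        one = fit_model(sim_choices, shared_hyperbolic, n_restarts=1, seed=3)
        many = fit_model(sim_choices, shared_hyperbolic, n_restarts=20, seed=3)
        assert many.neg_log_lik <= one.neg_log_lik + 1e-12

    def test_nested_model_never_fits_better(self, sim_choices):
        small = DiscountModelSpec(
            SharingClass.SHARED_K_SHARED_BETA, "hyperbolic", "hyperbolic"
        )
        large = DiscountModelSpec(
            SharingClass.SEPARATE_K_SEPARATE_BETA, "hyperbolic", "hyperbolic"
        )
        f_small = fit_model(sim_choices, small, n_restarts=15, seed=4)
        f_large = fit_model(sim_choices, large, n_restarts=15, seed=4)
        assert f_large.neg_log_lik <= f_small.neg_log_lik + 1e-6

    def test_all_offers_chosen_estimates_no_discounting(self, schedule, shared_hyperbolic):
        data = schedule.copy()
        data["subject"] = "s0"
        data["choice"] = "offer"
        fit = fit_model(data, shared_hyperbolic, n_restarts=10, seed=2)
        # with every offer accepted there is no discounting signal: the
        # estimate must keep even the cheapest offer (R=2, E=1) above baseline
        assert 2 / (1 + fit.params["k"]) >= 1.0 - 1e-6

    def test_aic_bic_closed_forms(self, sim_choices):
        for fit in fit_all_models(sim_choices, n_restarts=2, seed=1, xatol=1e-3, fatol=1e-5):
            p = fit.model.n_params
            assert fit.aic == pytest.approx(2 * p + 2 * fit.neg_log_lik)
            assert fit.bic == pytest.approx(p * np.log(fit.n_trials) + 2 * fit.neg_log_lik)
            assert fit.neg_log_lik >= 0

    def test_factorised_separate_beta_fit_matches_direct_call(self, sim_choices, winning_spec):
        direct = fit_model(sim_choices, winning_spec, n_restarts=4, seed=7)
        via_grid = [
            f
            for f in fit_all_models(sim_choices, n_restarts=4, seed=7)
            if f.model == winning_spec
        ][0]
        assert direct.params == via_grid.params
        assert direct.neg_log_lik == via_grid.neg_log_lik

    def test_invalid_restart_count_rejected(self, sim_choices, shared_hyperbolic):
        with pytest.raises(ValueError):
            fit_model(sim_choices, shared_hyperbolic, n_restarts=0)


def _make_fit(subject, model, nll, n_trials=150):
    return FitResult(
        subject=subject,
        model=model,
        params={},
        neg_log_lik=nll,
        n_trials=n_trials,
        n_restarts_converged=1,
    )


class TestCompareModels:
    def test_single_model_wins(self, shared_hyperbolic):
        fits = [_make_fit("a", shared_hyperbolic, 50.0), _make_fit("b", shared_hyperbolic, 60.0)]
        table = compare_models(fits, "aic")
        assert table.winner == shared_hyperbolic
        assert table.table.loc[0, "aic"] == pytest.approx(2 * 2 * 2 + 2 * 110.0)

    def test_tie_broken_toward_fewer_parameters(self):
        small = DiscountModelSpec(SharingClass.SHARED_K_SHARED_BETA, "linear", "linear")
        large = DiscountModelSpec(SharingClass.SEPARATE_K_SHARED_BETA, "linear", "linear")
        # equal AIC: 2*2 + 2*51 = 2*3 + 2*50
        fits = [_make_fit("a", small, 51.0), _make_fit("a", large, 50.0)]
        assert compare_models(fits, "aic").winner == small

    def test_incomplete_grid_rejected(self, shared_hyperbolic, winning_spec):
        fits = [
            _make_fit("a", shared_hyperbolic, 50.0),
            _make_fit("a", winning_spec, 48.0),
            _make_fit("b", shared_hyperbolic, 55.0),
        ]
        with pytest.raises(ValueError, match="missing"):
            compare_models(fits, "bic")

    def test_subject_winner_counts_sum_to_cohort(self, sim_choices):
        fits = fit_all_models(sim_choices, n_restarts=2, seed=1, xatol=1e-3, fatol=1e-5)
        table = compare_models(fits, "aic")
        assert table.table["n_subject_wins"].sum() == 1


class TestDifficultyIndex:
    @pytest.mark.parametrize("p,expected", [(0.5, 0.0), (1.0, -0.5), (0.0, -0.5), (0.25, -0.25)])
    def test_values(self, p, expected):
        assert difficulty_index(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            difficulty_index(1.2)
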