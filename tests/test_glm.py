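"""Logistic IRLS engine, LR tests and stepwise model building."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from pltr_immuno.cohort import CohortError
from pltr_immuno.glm import (build_design, fit_intercept_offset, fit_logistic,
                             irls_logistic, lr_test, stepwise_forward)
from pltr_immuno.simulate import SimConfig, generate_cohort
from tests.conftest import make_binary_cohort


def random_problem(rng, n=300, p=3, with_offset=False):
    X = np.column_stack([np.ones(n)] + [rng.binomial(1, 0.4, n).astype(float)
                                        for _ in range(p)])
    beta = rng.normal(0, 0.8, p + 1)
    off = rng.normal(0, 0.5, n) if with_offset else np.zeros(n)
    prob = 1 / (1 + np.exp(-(X @ beta + off)))
    y = (rng.random(n) < prob).astype(float)
    return X, y, off


class TestIrls:
    @pytest.mark.parametrize("with_offset", [False, True])
    def test_matches_statsmodels_glm(self, with_offset):
        rng = np.random.default_rng(1)
        X, y, off = random_problem(rng, with_offset=with_offset)
        beta, cov, dev, conv, _ = irls_logistic(X, y, offset=off)
        ref = sm.GLM(y, X, family=sm.families.Binomial(), offset=off).fit()
        assert conv
        assert beta == pytest.approx(ref.params, abs=1e-6)
        assert dev == pytest.approx(ref.deviance, abs=1e-8)
        assert np.diag(cov) == pytest.approx(
            np.diagonal(np.asarray(ref.cov_params())), rel=1e-4)

    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(58), np.zeros(67)]
        beta, _, _, conv, _ = irls_logistic(np.ones((125, 1)), y)
        assert conv
        assert beta[0] == pytest.approx(math.log(58 / 67), abs=1e-8)

    def test_saturated_two_by_two_reproduces_cell_log_odds(self):
        # cells (a,b,c,d) = (30,10,20,40): coefficient = log OR exactly
        x = np.r_[np.ones(40), np.zeros(60)]
        y = np.r_[np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)]
        X = np.column_stack([np.ones(100), x])
        beta, _, _, _, _ = irls_logistic(X, y)
        assert beta[0] == pytest.approx(math.log(20 / 40), abs=1e-8)
        assert beta[1] == pytest.approx(math.log((30 * 40) / (10 * 20)), abs=1e-7)

    def test_leaf_constant_matches_full_irls(self):
        rng = np.random.default_rng(4)
        y = rng.binomial(1, 0.4, 200).astype(float)
        off = rng.normal(0, 1, 200)
        c, dev = fit_intercept_offset(y, off)
        beta, _, dev_full, _, _ = irls_logistic(np.ones((200, 1)), y, offset=off)
        assert c == pytest.approx(beta[0], abs=1e-6)
        assert dev == pytest.approx(dev_full, abs=1e-8)


class TestFitLogistic:
    def test_single_binary_covariate_equals_cross_product_or(self):
        # DRB1*15 carrier counts: ML logistic equals the 2x2 odds ratio
        x = np.r_[np.ones(48), np.zeros(93)]
        y = np.r_[np.ones(31), np.zeros(17), np.ones(32), np.zeros(61)]
        cohort = make_binary_cohort(y, {"drb115": x})
        fit = fit_logistic(cohort, ["drb115"])
        assert round(math.exp(fit.coefficients["drb115[yes]"]), 2) == 3.48

    def test_offset_identity_reuses_previous_linear_predictor(self, medium_cohort):
        cohort, _ = medium_cohort
        fit = fit_logistic(cohort, ["f8_risk", "product_type"])
        X, _, _, rows = build_design(cohort, ["f8_risk", "product_type"])
        eta = fit.coefficients["(intercept)"] + X @ fit.beta[1:]
        refit = fit_logistic(cohort, [], offset=np.where(rows, 0, np.nan)[rows] * 0
                             + eta, rows=rows)
        assert refit.deviance == pytest.approx(fit.deviance, abs=1e-6)

    def test_information_criteria_definitions(self, medium_cohort):
        cohort, _ = medium_cohort
        fit = fit_logistic(cohort, ["f8_risk"])
        assert fit.aic == pytest.approx(fit.deviance + 2 * fit.p)
        assert fit.bic == pytest.approx(fit.deviance + fit.p * math.log(fit.n))
        assert fit.deviance == pytest.approx(-2 * fit.loglik)

    def test_coefficients_invariant_to_subject_order(self, medium_cohort):
        cohort, _ = medium_cohort
        fit1 = fit_logistic(cohort, ["f8_risk", "hla_drb1_15"])
        rng = np.random.default_rng(0)
        perm = rng.permutation(cohort.n)
        shuffled = cohort.subset(np.zeros(cohort.n, dtype=bool) | True)
        shuffled.data = shuffled.data.iloc[perm].reset_index(drop=True)
        fit2 = fit_logistic(shuffled, ["f8_risk", "hla_drb1_15"])
        for k in fit1.coefficients:
            assert fit1.coefficients[k] == pytest.approx(fit2.coefficients[k],
                                                         abs=1e-7)

    def test_deviance_non_increasing_under_term_addition(self, medium_cohort):
        cohort, _ = medium_cohort
        terms = ["f8_risk", "family_history", "hla_drb1_15", "product_type"]
        rows = build_design(cohort, terms)[3]
        prev = np.inf
        for k in range(len(terms) + 1):
            fit = fit_logistic(cohort, terms[:k], rows=rows)
            assert fit.deviance <= prev + 1e-8
            prev = fit.deviance

    def test_separation_is_flagged(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        cohort = make_binary_cohort(x, {"x": x})  # outcome == x: separated
        with pytest.warns(RuntimeWarning, match="separation"):
            fit = fit_logistic(cohort, ["x"])
        assert not fit.converged


class TestLrTest:
    def test_identical_models_give_p_one(self, medium_cohort):
        cohort, _ = medium_cohort
        fit = fit_logistic(cohort, ["f8_risk"])
        assert lr_test(fit, fit) == 1.0

    def test_non_nested_designs_are_fatal(self, medium_cohort):
        cohort, _ = medium_cohort
        rows = build_design(cohort, ["f8_risk", "product_type"])[3]
        f1 = fit_logistic(cohort, ["f8_risk"], rows=rows)
        f2 = fit_logistic(cohort, ["product_type"], rows=rows)
        with pytest.raises(CohortError):
            lr_test(f1, f2)

    def test_power_against_a_strong_planted_effect(self):
        rng = np.random.default_rng(6)
        detected = 0
        for _ in range(20):
            x = rng.binomial(1, 0.4, 500)
            prob = 1 / (1 + np.exp(-(-0.8 + math.log(4) * x)))
            y = (rng.random(500) < prob).astype(int)
            cohort = make_binary_cohort(y, {"x": x})
            full = fit_logistic(cohort, ["x"])
            null = fit_logistic(cohort, [])
            detected += lr_test(null, full) < 0.001
        assert detected >= 19

    def test_null_rejection_rate_close_to_nominal(self):
        rng = np.random.default_rng(8)
        rej, reps = 0, 400
        for _ in range(reps):
            x = rng.binomial(1, 0.5, 400)
            y = rng.binomial(1, 0.5, 400)
            cohort = make_binary_cohort(y, {"x": x})
            rej += lr_test(fit_logistic(cohort, []),
                           fit_logistic(cohort, ["x"])) < 0.05
        assert 0.03 <= rej / reps <= 0.08


class TestStepwiseForward:
    def test_single_strong_candidate_enters(self):
        rng = np.random.default_rng(9)
        x = rng.binomial(1, 0.4, 400)
        prob = 1 / (1 + np.exp(-(-0.5 + 1.2 * x)))
        y = (rng.random(400) < prob).astype(int)
        cohort = make_binary_cohort(y, {"x": x})
        fit, trace = stepwise_forward(cohort, ["x"])
        assert fit.terms == ("x",)
        assert sum(t["action"] == "enter" for t in trace) == 1

    def test_collinear_candidates_only_one_enters(self):
        # DRB1*15 and DQB1*06 carriers are strongly correlated; the planted
        # effect acts through DRB1*15 and exactly one of the pair is kept.
        cohort, _ = generate_cohort(SimConfig(n=800, seed=13))
        fit, _ = stepwise_forward(
            cohort, ["hla_drb1_15", "hla_dqb1_06"],
            always_in=["f8_risk", "family_history", "product_type"])
        entered = [t for t in fit.terms if t.startswith("hla_")]
        assert len(entered) == 1

    def test_all_null_candidates_keep_base_model(self):
        # with two null candidates, the base model survives in ~0.95^2 = 90%
        # of cohorts; 16/20 is the lower 2-sigma bound of that rate
        rng = np.random.default_rng(31)
        kept_base = 0
        for _ in range(20):
            y = rng.binomial(1, 0.5, 1000)
            cols = {f"x{i}": rng.binomial(1, 0.4, 1000) for i in range(2)}
            cohort = make_binary_cohort(y, cols)
            fit, _ = stepwise_forward(cohort, sorted(cols))
            kept_base += fit.terms == ()
        assert kept_base >= 16

    def test_empty_prefilter_returns_base_with_note(self):
        rng = np.random.default_rng(41)
        y = rng.binomial(1, 0.5, 300)
        x = y * 0  # constant, cannot pass any filter
        cohort = make_binary_cohort(y, {"x": rng.binomial(1, 0.5, 300)})
        fit, trace = stepwise_forward(cohort, ["x"], prefilter=1e-9)
        assert fit.terms == ()
        assert trace[-1]["action"] == "note"
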