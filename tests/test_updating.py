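"""Update-model fitting, likelihood-ratio tests, and the closed test."""

from dataclasses import replace

import numpy as np
import pytest

import decaval as dv
from decaval.errors import DegenerateDataError
from decaval.updating import UPDATE_VARIANTS


def _loglik(y, lp):
    return float(np.sum(y * lp - np.logaddexp(0.0, lp)))


class TestFitUpdateModel:
    def test_free_parameter_counts(self, cohort_273, true_model):
        expected = {
            "original": 0,
            "calibration_in_the_large": 1,
            "logistic_calibration": 2,
            "revision": 6,
        }
        for variant, k in expected.items():
            fit = dv.fit_update_model(cohort_273, true_model, variant)
            assert fit.n_free_params == k, variant
            assert fit.log_likelihood <= 0.0
            assert fit.n_obs == 273

    def test_original_loglik_evaluated_at_fixed_coefficients(
        self, cohort_273, true_model
    ):
        fit = dv.fit_update_model(cohort_273, true_model, "original")
        from scipy.special import logit

        p = dv.predict_probability(cohort_273.data, true_model)
        ll = _loglik(cohort_273.outcome.astype(float), logit(p))
        assert fit.log_likelihood == pytest.approx(ll, abs=1e-9)
        assert fit.coefficients is true_model

    def test_nesting_chain_of_likelihoods(self, cohort_273, true_model):
        lls = [
            dv.fit_update_model(cohort_273, true_model, v).log_likelihood
            for v in UPDATE_VARIANTS
        ]
        for smaller, larger in zip(lls, lls[1:]):
            assert larger >= smaller - 1e-6

    def test_citl_intercept_near_zero_under_truth(self, cohort_5000, true_model):
        fit = dv.fit_update_model(cohort_5000, true_model, "calibration_in_the_large")
        delta = fit.free_params["delta_intercept"]
        se = fit.standard_errors["delta_intercept"]
        assert abs(delta) < 3 * se

    def test_slope_recovery_under_shrinkage(self, true_model):
        gamma = 0.5
        cfg = dv.SimulationConfig(
            n_patients=20_000, seed=31,
            scenario=dv.Scenario("slope_shrinkage", gamma),
        )
        cohort = dv.generate_cohort(cfg)
        fit = dv.fit_update_model(cohort, true_model, "logistic_calibration")
        slope = fit.free_params["slope"]
        se = fit.standard_errors["slope"]
        assert abs(slope - gamma) < 3 * se

    def test_recalibration_folds_into_predictor_space(self, cohort_273, true_model):
        # predictions from the folded coefficient set equal expit(a + b * lp_orig)
        from scipy.special import expit, logit

        fit = dv.fit_update_model(cohort_273, true_model, "logistic_calibration")
        a, b = fit.free_params["intercept"], fit.free_params["slope"]
        lp_orig = logit(dv.predict_probability(cohort_273.data, true_model))
        np.testing.assert_allclose(
            fit.predict(cohort_273), expit(a + b * lp_orig), atol=1e-12
        )

    def test_single_class_outcome_rejected(self, cohort_273, true_model):
        df = cohort_273.data.copy()
        df["decannulated"] = 1
        with pytest.raises(DegenerateDataError, match="single class"):
            dv.fit_update_model(df, true_model, "revision")

    def test_separation_advises_ridge(self, true_model):
        # a covariate pattern that perfectly predicts the outcome
        cfg = dv.SimulationConfig(n_patients=200, seed=8)
        df = dv.generate_cohort(cfg).data.copy()
        df["decannulated"] = (df["cough_class"] == "voluntary_and_reflex").astype(int)
        with pytest.raises(dv.SeparationError, match="ridge"):
            dv.fit_update_model(df, true_model, "revision")
        fit = dv.fit_update_model(df, true_model, "revision", ridge=True)
        assert fit.used_ridge
        assert np.isfinite(fit.log_likelihood)


class TestLRTest:
    def test_df_triple(self, cohort_273, true_model):
        fits = {
            v: dv.fit_update_model(cohort_273, true_model, v) for v in UPDATE_VARIANTS
        }
        assert dv.lr_test(fits["revision"], fits["original"]).df == 6
        assert dv.lr_test(fits["revision"], fits["calibration_in_the_large"]).df == 5
        assert dv.lr_test(fits["revision"], fits["logistic_calibration"]).df == 4

    def test_statistic_equals_recomputed_loglik_difference(self, true_model):
        from scipy.special import logit

        cfg = dv.SimulationConfig(n_patients=20, seed=77)
        cohort = dv.generate_cohort(cfg)
        y = cohort.outcome.astype(float)
        full = dv.fit_update_model(cohort, true_model, "logistic_calibration")
        reduced = dv.fit_update_model(cohort, true_model, "original")
        # recompute both log-likelihoods directly from the coefficient sets
        ll_full = _loglik(y, logit(dv.predict_probability(cohort.data, full.coefficients)))
        ll_red = _loglik(y, logit(dv.predict_probability(cohort.data, true_model)))
        test = dv.lr_test(full, reduced)
        assert test.statistic == pytest.approx(2 * (ll_full - ll_red), abs=1e-9)
        assert 0 <= test.p_value <= 1

    def test_statistic_nonnegative(self, cohort_273, true_model):
        full = dv.fit_update_model(cohort_273, true_model, "revision")
        for v in ("original", "calibration_in_the_large", "logistic_calibration"):
            reduced = dv.fit_update_model(cohort_273, true_model, v)
            assert dv.lr_test(full, reduced).statistic >= 0.0

    def test_non_nested_rejected(self, cohort_273, true_model):
        rev = dv.fit_update_model(cohort_273, true_model, "revision")
        cont = dv.fit_extended_model(cohort_273, "continuous")
        with pytest.raises(ValueError, match="nested"):
            dv.lr_test(rev, cont)
        with pytest.raises(ValueError, match="nested"):
            dv.lr_test(rev, rev)


class TestClosedTest:
    def test_perturbation_routes_to_revision(self):
        cfg = dv.SimulationConfig(
            n_patients=2000, seed=55,
            scenario=dv.Scenario("coefficient_perturbation", 0.8),
        )
        cohort = dv.generate_cohort(cfg)
        out = dv.closed_test_select(cohort, dv.synthetic_decapret_model())
        assert out.selected == "revision"
        assert all(t.p_value < out.alpha for t in out.tests)
        assert [t.df for t in out.tests] == [6, 5, 4]

    def test_intercept_shift_routes_to_citl(self):
        # pure prevalence drift: intercept-only recalibration suffices, so it
        # is selected except for chance rejections of its (true) null test
        wins = 0
        for s in range(10):
            cfg = dv.SimulationConfig(
                n_patients=5000, seed=560 + s,
                scenario=dv.Scenario("intercept_shift", 1.0),
            )
            out = dv.closed_test_select(
                dv.generate_cohort(cfg), dv.synthetic_decapret_model()
            )
            wins += out.selected == "calibration_in_the_large"
        assert wins > 5

    def test_selection_is_deterministic(self, cohort_273, true_model):
        a = dv.closed_test_select(cohort_273, true_model)
        b = dv.closed_test_select(cohort_273, true_model)
        assert a.selected == b.selected
        assert [t.statistic for t in a.tests] == [t.statistic for t in b.tests]


class TestExtendedModels:
    def test_parameter_counts(self, cohort_273):
        assert dv.fit_extended_model(cohort_273, "continuous").n_free_params == 6
        assert dv.fit_extended_model(cohort_273, "complete").n_free_params == 7

    def test_complete_recovers_generating_coefficients(self):
        truth = dv.CoefficientSet(
            intercept=1.0,
            coefficients={
                "age_years": -0.03, "crs_r": 0.12, "saliva_score": -1.0,
                "cough_score": 0.7, "pathogenesis_score": 0.4,
                "icu_los_days": -0.02,
            },
            provenance="true_synthetic",
        )
        cfg = dv.SimulationConfig(n_patients=20_000, seed=90, true_model=truth)
        fit = dv.fit_extended_model(dv.generate_cohort(cfg), "complete")
        for name, beta in truth.coefficients.items():
            est = fit.coefficients.coefficients[name]
            se = fit.standard_errors[name]
            assert abs(est - beta) < 3 * se, name

    def test_null_icu_coefficient_within_noise(self):
        # truth has no ICU effect: the complete-model estimate straddles zero
        cfg = dv.SimulationConfig(n_patients=20_000, seed=91)
        fit = dv.fit_extended_model(dv.generate_cohort(cfg), "complete")
        est = fit.coefficients.coefficients["icu_los_days"]
        assert abs(est) < 3 * fit.standard_errors["icu_los_days"]
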