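"""Metric battery: Brier, AUC, calibration, smoothing, NRI, IDI."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import decaval as dv
from decaval.errors import DegenerateDataError, ValidationError


def brute_force_auc(p, y):
    """Exhaustive pairwise concordance with half credit for ties."""
    p = np.asarray(p)
    y = np.asarray(y)
    events = p[y == 1]
    nonevents = p[y == 0]
    total = 0.0
    for pe in events:
        for pn in nonevents:
            if pe > pn:
                total += 1.0
            elif pe == pn:
                total += 0.5
    return total / (len(events) * len(nonevents))


@st.composite
def prediction_instances(draw):
    n = draw(st.integers(4, 50))
    # coarse grid encourages ties, exercising the half-credit rule
    p = draw(
        st.lists(
            st.sampled_from([0.1, 0.2, 0.3, 0.5, 0.7, 0.8, 0.9]),
            min_size=n, max_size=n,
        )
    )
    y = draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if len(set(y)) < 2:
        y[0], y[-1] = 0, 1
    return np.array(p), np.array(y)


class TestBrier:
    def test_perfect_and_constant_forecasts(self):
        y = np.array([0, 1, 1, 0])
        near = np.array([1e-12, 1 - 1e-12, 1 - 1e-12, 1e-12])
        assert dv.brier_score(near, y) == pytest.approx(0.0, abs=1e-20)
        assert dv.brier_score(np.full(4, 0.5), y) == pytest.approx(0.25)

    def test_hand_arithmetic(self):
        got = dv.brier_score([0.2, 0.7, 0.9], [0, 1, 1])
        assert got == pytest.approx((0.04 + 0.09 + 0.01) / 3, abs=1e-15)

    def test_constant_mean_forecast_equals_outcome_variance(self, rng):
        y = (rng.random(500) < 0.4).astype(float)
        m = y.mean()
        assert dv.brier_score(np.full_like(y, m), y) == pytest.approx(
            m * (1 - m), abs=1e-12
        )


class TestAUC:
    def test_perfectly_separated(self):
        assert dv.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_predictions_are_all_ties(self):
        assert dv.auc(np.full(6, 0.4), [0, 1, 0, 1, 0, 1]) == 0.5

    @given(prediction_instances())
    def test_equals_brute_force_concordance(self, inst):
        p, y = inst
        assert dv.auc(p, y) == pytest.approx(brute_force_auc(p, y), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            dv.auc([0.2, 0.4], [1, 1])


class TestCalibrationInterceptSlope:
    def test_refit_model_is_apparently_calibrated(self, cohort_273, true_model):
        fit = dv.fit_update_model(cohort_273, true_model, "revision")
        p = np.clip(fit.predict(cohort_273), 1e-10, 1 - 1e-10)
        intercept, slope = dv.calibration_intercept_slope(p, cohort_273.outcome)
        assert intercept == pytest.approx(0.0, abs=1e-6)
        assert slope == pytest.approx(1.0, abs=1e-6)

    def test_recovers_logit_scale_distortion(self, rng):
        # predictions shrunk by half on the logit scale have calibration slope 2
        n = 50_000
        from scipy.special import expit, logit

        lp = rng.normal(0.0, 1.5, n)
        y = (rng.random(n) < expit(lp)).astype(float)
        p_shrunk = expit(0.5 * lp)
        _, slope = dv.calibration_intercept_slope(p_shrunk, y)
        # binomial-regression SE of the slope is ~ O(1/sqrt(n)) here
        assert slope == pytest.approx(2.0, abs=0.1)

    def test_recovers_intercept_shift(self, rng):
        n = 50_000
        from scipy.special import expit

        delta = 0.7
        lp = rng.normal(0.0, 1.0, n)
        y = (rng.random(n) < expit(lp + delta)).astype(float)
        intercept, _ = dv.calibration_intercept_slope(expit(lp), y)
        assert intercept == pytest.approx(delta, abs=0.08)

    def test_constant_predictions_rejected(self):
        with pytest.raises(DegenerateDataError, match="slope"):
            dv.calibration_intercept_slope(np.full(30, 0.4), np.arange(30) % 2)


class TestCalibrationCurve:
    def test_smoother_consistent_under_perfect_calibration(self, rng):
        n = 50_000
        p = rng.uniform(0.05, 0.95, n)
        y = (rng.random(n) < p).astype(float)
        curve = dv.calibration_curve(p, y)
        assert np.max(np.abs(curve.smoothed - curve.points)) < 0.02

    def test_constant_predictions_yield_mean_outcome(self):
        p = np.full(40, 0.3)
        y = np.r_[np.ones(10), np.zeros(30)]
        curve = dv.calibration_curve(p, y)
        assert curve.points.tolist() == [0.3]
        assert curve.smoothed.tolist() == [0.25]

    def test_deciles_partition_cohort(self, cohort_273, true_model):
        p = np.clip(
            dv.predict_probability(cohort_273.data, true_model), 1e-10, 1 - 1e-10
        )
        curve = dv.calibration_curve(p, cohort_273.outcome)
        assert curve.deciles["n"].sum() == len(cohort_273)
        assert len(curve.deciles) == 10

    def test_small_sample_rejected(self):
        with pytest.raises(DegenerateDataError, match="decile"):
            dv.calibration_curve(np.linspace(0.1, 0.9, 10), np.arange(10) % 2)


class TestEmaxICI:
    def test_zero_under_perfect_smooth(self):
        p = np.linspace(0.05, 0.95, 100)
        y = (p > 0.5).astype(float)
        curve = dv.calibration_curve(p, y)
        # replace the smooth by the identity: no calibration error left
        from dataclasses import replace as dc_replace

        ideal = dc_replace(curve, smoothed=curve.points.copy())
        e_max, ici = dv.emax_ici(ideal, p, y)
        assert e_max == 0.0 and ici == 0.0

    def test_ici_never_exceeds_emax(self, rng):
        for _ in range(5):
            n = 500
            p = rng.uniform(0.05, 0.95, n)
            y = (rng.random(n) < np.clip(p + 0.1, 0, 1)).astype(float)
            curve = dv.calibration_curve(p, y)
            e_max, ici = dv.emax_ici(curve, p, y)
            assert 0.0 <= ici <= e_max <= 1.0

    def test_known_additive_miscalibration_recovered(self, rng):
        n = 50_000
        p_true = rng.uniform(0.10, 0.85, n)
        y = (rng.random(n) < p_true).astype(float)
        p_shifted = p_true + 0.05
        curve = dv.calibration_curve(p_shifted, y)
        _, ici = dv.emax_ici(curve, p_shifted, y)
        assert ici == pytest.approx(0.05, abs=0.01)

    def test_mismatched_inputs_rejected(self, rng):
        p = rng.uniform(0.1, 0.9, 100)
        y = (rng.random(100) < p).astype(float)
        curve = dv.calibration_curve(p, y)
        with pytest.raises(ValidationError, match="different prediction"):
            dv.emax_ici(curve, p[:50], y[:50])


class TestReclassification:
    def test_self_comparison_is_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 50)
        y = np.arange(50) % 2
        assert dv.nri_continuous(p, p, y) == (0.0, 0.0, 0.0)
        assert dv.idi(p, p, y) == 0.0

    def test_maximal_improvement(self):
        y = np.array([1, 1, 0, 0])
        p_old = np.array([0.5, 0.5, 0.5, 0.5])
        p_new = np.array([0.7, 0.9, 0.2, 0.1])
        assert dv.nri_continuous(p_new, p_old, y)[2] == pytest.approx(2.0)

    def test_hand_counted_six_subject_example(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        p_old = np.full(6, 0.5)
        p_new = np.array([0.6, 0.7, 0.4, 0.3, 0.6, 0.5])
        # events: 2 up, 1 down -> 1/3; non-events: 1 down, 1 up, 1 tie -> 0
        ev, ne, tot = dv.nri_continuous(p_new, p_old, y)
        assert ev == pytest.approx(1 / 3)
        assert ne == pytest.approx(0.0)
        assert tot == pytest.approx(1 / 3)

    def test_hand_computed_idi(self):
        y = np.array([1, 1, 0, 0])
        p_old = np.array([0.6, 0.4, 0.5, 0.3])
        p_new = np.array([0.7, 0.5, 0.4, 0.2])
        # discrimination slopes: new 0.6-0.3=0.3, old 0.5-0.4=0.1
        assert dv.idi(p_new, p_old, y) == pytest.approx(0.2, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        p_a = rng.uniform(0.05, 0.95, n)
        p_b = rng.uniform(0.05, 0.95, n)
        ev, ne, tot = dv.nri_continuous(p_a, p_b, y)
        ev2, ne2, tot2 = dv.nri_continuous(p_b, p_a, y)
        assert (ev2, ne2, tot2) == pytest.approx((-ev, -ne, -tot), abs=1e-12)
        assert dv.idi(p_b, p_a, y) == pytest.approx(-dv.idi(p_a, p_b, y), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="length"):
            dv.nri_continuous([0.1, 0.2], [0.1], [1, 0])
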