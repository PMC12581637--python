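"""Discrimination and calibration statistics against independent oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from sahitval.metrics import (
    MetricError,
    UndefinedMetricError,
    auc,
    auc_ci,
    brier,
    calibration_curve,
    calibration_intercept,
    calibration_slope,
    fit_logistic_1d,
    recalibration_fit,
    roc_points,
    validation_report,
)


def auc_by_pair_enumeration(p, y):
    """Independent oracle: exhaustive loop over all event/non-event pairs."""
    pos = [pi for pi, yi in zip(p, y) if yi == 1]
    neg = [pi for pi, yi in zip(p, y) if yi == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_score_is_half(self):
        assert auc([0.3] * 6, [1, 0, 1, 0, 0, 1]) == 0.5

    def test_example_and_oracle(self):
        p, y = [0.9, 0.4, 0.6, 0.1], [1, 0, 1, 0]
        assert auc(p, y) == 1.0
        assert auc(p, y) == auc_by_pair_enumeration(p, y)

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=2, max_size=10),
        st.data(),
    )
    def test_equals_pair_enumeration_small_n(self, p, data):
        y = data.draw(st.lists(st.integers(0, 1), min_size=len(p), max_size=len(p)))
        if sum(y) in (0, len(y)):
            y[0] = 1 - y[0]
        assert auc(p, y) == pytest.approx(auc_by_pair_enumeration(p, y), abs=1e-12)

    @given(st.lists(st.floats(0.01, 0.99), min_size=3, max_size=10))
    def test_invariant_under_monotone_transform(self, p):
        y = [i % 2 for i in range(len(p))]
        transformed = [0.2 + 0.6 * expit(3 * x) for x in p]
        assert auc(p, y) == pytest.approx(auc(transformed, y), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.2, 0.4], [1, 1])

    def test_trapezoid_under_roc_matches(self, rng):
        p = rng.random(200)
        y = (rng.random(200) < p).astype(int)
        fpr, tpr, _ = roc_points(p, y)
        assert np.trapezoid(tpr, fpr) == pytest.approx(auc(p, y), abs=1e-12)


class TestAucCI:
    def test_interval_covers_large_sample_auc(self, rng):
        n = 2000
        lp = rng.normal(-1.0, 1.2, n)
        y = (rng.random(n) < expit(lp)).astype(int)
        p = expit(lp)
        lo, hi = auc_ci(p, y, 0.95)
        # the population concordance, estimated once at large n
        big_lp = np.random.default_rng(0).normal(-1.0, 1.2, 200_000)
        big_y = (np.random.default_rng(1).random(200_000) < expit(big_lp)).astype(int)
        truth = auc(expit(big_lp), big_y)
        assert lo <= truth <= hi

    def test_perfect_separation_clips_at_one(self):
        lo, hi = auc_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 0.95)
        assert hi == 1.0
        assert lo <= 1.0

    def test_duplicated_data_narrows_interval(self, rng):
        p = rng.random(80)
        y = (rng.random(80) < p).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        lo1, hi1 = auc_ci(p, y)
        lo2, hi2 = auc_ci(np.tile(p, 2), np.tile(y, 2))
        assert hi2 - lo2 < hi1 - lo1

    def test_bootstrap_close_to_delong(self, rng):
        n = 400
        p = rng.random(n)
        y = (rng.random(n) < p).astype(int)
        lo_d, hi_d = auc_ci(p, y, method="delong")
        lo_b, hi_b = auc_ci(p, y, method="bootstrap", rng=np.random.default_rng(5))
        assert lo_b == pytest.approx(lo_d, abs=0.05)
        assert hi_b == pytest.approx(hi_d, abs=0.05)

    def test_delong_matches_sklearn_point(self, rng):
        from sklearn.metrics import roc_auc_score

        p = rng.random(300)
        y = (rng.random(300) < p).astype(int)
        assert auc(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)


class TestBrier:
    def test_constant_half_scores_quarter(self):
        assert brier([0.5] * 5, [1, 0, 0, 1, 1]) == 0.25

    def test_perfect_forecast_is_zero(self):
        assert brier([1 - 1e-12, 1e-12], [1, 0]) == pytest.approx(0.0, abs=1e-20)

    def test_hand_arithmetic(self):
        assert brier([0.8, 0.2], [1, 0]) == pytest.approx(0.04, abs=1e-12)

    @given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=20))
    def test_complement_symmetry(self, p):
        y = [i % 2 for i in range(len(p))]
        assert brier(p, y) == pytest.approx(
            brier([1 - x for x in p], [1 - v for v in y]), abs=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricError):
            brier([0.5, 0.5], [1])


class TestLogisticFit:
    def test_intercept_only_closed_form(self):
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        fit = fit_logistic_1d(None, y)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(logit(0.3), abs=1e-8)

    def test_parameter_recovery_within_3se(self, rng):
        n = 50_000
        x = rng.normal(0, 1, n)
        y = (rng.random(n) < expit(0.4 + 0.9 * x)).astype(int)
        fit = fit_logistic_1d(x, y)
        assert fit.converged
        assert abs(fit.coef[0] - 0.4) < 3 * fit.se[0]
        assert abs(fit.coef[1] - 0.9) < 3 * fit.se[1]

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm

        for trial in range(5):
            r = np.random.default_rng(100 + trial)
            n = 80
            x = r.normal(0, 1.5, n)
            off = r.normal(0, 0.5, n)
            y = (r.random(n) < expit(-0.3 + 0.7 * x + off)).astype(int)
            if y.min() == y.max():
                continue
            ours = fit_logistic_1d(x, y, offset=off)
            X = sm.add_constant(x)
            ref = sm.GLM(y, X, family=sm.families.Binomial(), offset=off).fit()
            np.testing.assert_allclose(ours.coef, ref.params, atol=1e-6)
            np.testing.assert_allclose(ours.se, ref.bse, atol=1e-6)

    def test_separation_flagged_not_converged(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        fit = fit_logistic_1d(x, y)
        assert not fit.converged
        assert fit.message

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            fit_logistic_1d(None, [1, 1, 1])


class TestCalibration:
    def test_intercept_near_zero_when_calibrated(self, rng):
        n = 100_000
        lp = rng.normal(-1.2, 1.0, n)
        y = (rng.random(n) < expit(lp)).astype(int)
        est = calibration_intercept(lp, y)
        assert abs(est.value) < 3 * est.se
        assert est.low <= est.value <= est.high

    def test_intercept_recovers_injected_shift(self, rng):
        n = 100_000
        lp = rng.normal(-1.2, 1.0, n)
        y = (rng.random(n) < expit(lp + 0.44)).astype(int)
        est = calibration_intercept(lp, y)
        assert est.value == pytest.approx(0.44, abs=0.03)

    def test_intercept_positive_when_risks_shrunk_below_observed(self, rng):
        # events from lp with positive mean; halving the logit pulls the
        # predictions below the observed rate -> systematic under-estimation
        n = 20_000
        lp = rng.normal(1.0, 1.0, n)
        y = (rng.random(n) < expit(lp)).astype(int)
        est = calibration_intercept(lp / 2, y)
        assert est.value > 0

    def test_slope_near_one_when_calibrated(self, rng):
        n = 100_000
        lp = rng.normal(-1.0, 1.3, n)
        y = (rng.random(n) < expit(lp)).astype(int)
        est = calibration_slope(lp, y)
        assert abs(est.value - 1.0) < 3 * est.se

    def test_slope_recovers_085(self, rng):
        n = 100_000
        lp = rng.normal(-1.0, 1.3, n)
        y = (rng.random(n) < expit(0.85 * lp)).astype(int)
        est = calibration_slope(lp, y)
        assert est.value == pytest.approx(0.85, abs=0.03)

    def test_slope_halves_under_doubled_lp(self, rng):
        n = 50_000
        lp = rng.normal(0, 1.0, n)
        y = (rng.random(n) < expit(lp)).astype(int)
        b1 = calibration_slope(lp, y).value
        b2 = calibration_slope(2 * lp, y).value
        assert b2 == pytest.approx(b1 / 2, rel=1e-6)

    def test_constant_lp_undefined_slope(self):
        with pytest.raises(UndefinedMetricError):
            calibration_slope([0.7] * 10, [1, 0] * 5)


class TestCalibrationCurve:
    def test_counts_partition_n(self, rng):
        p = rng.random(97)
        y = (rng.random(97) < p).astype(int)
        bins = calibration_curve(p, y, n_bins=10)
        assert sum(b.count for b in bins) == 97

    def test_all_events_rate_one(self, rng):
        p = rng.random(40)
        bins = calibration_curve(p, np.ones(40, dtype=int), n_bins=4)
        assert all(b.observed_rate == 1.0 for b in bins)

    def test_calibrated_large_sample_close_to_diagonal(self, rng):
        n = 50_000
        p = expit(rng.normal(-0.5, 1.0, n))
        y = (rng.random(n) < p).astype(int)
        bins = calibration_curve(p, y, n_bins=10)
        assert max(abs(b.mean_predicted - b.observed_rate) for b in bins) < 0.03

    def test_too_many_bins_rejected(self):
        with pytest.raises(MetricError):
            calibration_curve([0.2, 0.8], [0, 1], n_bins=3)

    def test_tied_probabilities_merge_bins(self):
        p = [0.3] * 50 + [0.7] * 50
        y = [0] * 50 + [1] * 50
        bins = calibration_curve(p, y, n_bins=10)
        assert len(bins) == 2
        assert sum(b.count for b in bins) == 100


class TestValidationReport:
    def test_composition_equals_individual_metrics(self, rng):
        n = 500
        lp = rng.normal(-1, 1, n)
        p = expit(lp)
        y = (rng.random(n) < p).astype(int)
        rep = validation_report(p, lp, y, "mortality", "full")
        assert rep.auc.value == auc(p, y)
        assert rep.brier == brier(p, y)
        assert rep.cal_intercept.value == calibration_intercept(lp, y).value
        assert rep.cal_slope.value == calibration_slope(lp, y).value
        assert rep.n == n and rep.events == y.sum()
        assert sum(b.count for b in rep.curve) == n

    def test_empty_cohort_refused(self):
        with pytest.raises(MetricError):
            validation_report([], [], [], "mortality", "full")

    def test_joint_recalibration_reported_consistently(self, rng):
        n = 5000
        lp = rng.normal(-1, 1, n)
        y = (rng.random(n) < expit(lp)).astype(int)
        fit = recalibration_fit(lp, y)
        assert calibration_slope(lp, y).value == fit.coef[1]
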