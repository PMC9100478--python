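"""Successive-dichotomization calibration: reduction, symmetry, recovery."""
import numpy as np
import pytest

import msdvfq as mv
from msdvfq.exceptions import CalibrationError, DataValidationError
from msdvfq.msd import estimate_thresholds


def simulated(seed, n=300, b=None, tau=None, **kw):
    config = mv.SimulationConfig(
        seed=seed,
        n_persons=n,
        item_measures=b,
        thresholds=tau,
        **kw,
    )
    return mv.simulate_responses(config), config


class TestDichotomize:
    def test_cut_definition(self):
        matrix = mv.RatingMatrix(np.array([[0.0, 1.0, 2.0, 3.0, 4.0]]), 4)
        np.testing.assert_array_equal(
            mv.dichotomize(matrix, 3)[0], [0.0, 0.0, 0.0, 1.0, 1.0]
        )

    def test_bottom_and_top_categories(self):
        matrix = mv.RatingMatrix(np.array([[0.0, 4.0], [4.0, 0.0]]), 4)
        for k in range(1, 5):
            cut = mv.dichotomize(matrix, k)
            assert cut[0, 0] == 0.0 and cut[0, 1] == 1.0

    def test_missing_stays_missing(self):
        matrix = mv.RatingMatrix(np.array([[np.nan, 2.0], [1.0, 0.0]]), 4)
        assert np.isnan(mv.dichotomize(matrix, 1)[0, 0])

    def test_out_of_range_cut_rejected(self):
        matrix = mv.RatingMatrix(np.array([[0.0, 1.0]]), 1)
        with pytest.raises(DataValidationError):
            mv.dichotomize(matrix, 2)


class TestCalibrate:
    def test_binary_reduction_equals_dichotomous_fit(self):
        rng = np.random.default_rng(3)
        X = (rng.uniform(size=(40, 6)) < 0.5).astype(float)
        cal = mv.msd_calibrate(mv.RatingMatrix(X, 1))
        fit = mv.fit_dichotomous(X)
        np.testing.assert_allclose(
            cal.item_measures, fit.item_difficulties, atol=1e-10
        )
        np.testing.assert_allclose(
            cal.person_measures, fit.person_abilities, atol=1e-8
        )
        assert cal.thresholds[0] == pytest.approx(0.0, abs=1e-6)

    def test_mean_item_measure_is_zero(self):
        matrix, _ = simulated(31)
        cal = mv.msd_calibrate(matrix)
        assert abs(np.nanmean(cal.item_measures)) < 1e-6

    def test_thresholds_strictly_increasing(self):
        for seed in (5, 6, 7):
            matrix, _ = simulated(seed)
            cal = mv.msd_calibrate(matrix)
            assert np.all(np.diff(cal.thresholds) > 0)

    def test_category_reversal_symmetry(self):
        matrix, _ = simulated(
            8,
            n=120,
            b=np.linspace(-1.5, 1.5, 8),
            tau=np.array([-1.2, -0.2, 0.7, 1.8]),
            person_mean=0.3,
            person_sd=1.5,
        )
        cal = mv.msd_calibrate(matrix)
        reversed_values = np.where(
            np.isfinite(matrix.values), matrix.m - matrix.values, np.nan
        )
        cal_rev = mv.msd_calibrate(
            mv.RatingMatrix(reversed_values, matrix.m, matrix.person_ids)
        )
        np.testing.assert_allclose(
            cal.item_measures, -cal_rev.item_measures, atol=1e-6
        )
        np.testing.assert_allclose(
            cal.thresholds, -cal_rev.thresholds[::-1], atol=1e-6
        )
        np.testing.assert_allclose(
            cal.person_measures, -cal_rev.person_measures, atol=1e-6
        )

    def test_uniform_extreme_persons_missing(self):
        values = np.vstack(
            [np.full(6, 4.0), np.full(6, 0.0), np.tile([1.0, 3.0], 3)]
            + [np.random.default_rng(9).integers(0, 5, 6).astype(float)] * 5
        )
        cal = mv.msd_calibrate(mv.RatingMatrix(values, 4))
        assert np.isnan(cal.person_measures[0])
        assert np.isnan(cal.person_measures[1])
        assert np.isfinite(cal.person_measures[2])

    def test_item_recovery_500_persons(self, sim_500, cal_500):
        """Generating item measures are recovered from 500 simulated
        persons with high fidelity."""
        _, config = sim_500
        truth = config.item_measures - config.item_measures.mean()
        est = cal_500.item_measures
        assert np.corrcoef(truth, est)[0, 1] > 0.97
        assert np.sqrt(np.mean((truth - est) ** 2)) < 0.15

    def test_missing_data_invariance(self, sim_500, cal_500):
        """Deleting 20% of responses moves item measures by less than
        twice the reported standard errors on average."""
        matrix, _ = sim_500
        rng = np.random.default_rng(99)
        thinned = np.where(
            rng.uniform(size=matrix.values.shape) < 0.2, np.nan, matrix.values
        )
        cal2 = mv.msd_calibrate(mv.RatingMatrix(thinned, matrix.m))
        shift = np.abs(cal_500.item_measures - cal2.item_measures).mean()
        assert shift < 2.0 * np.nanmean(cal_500.item_se)

    def test_no_estimable_dichotomization_raises(self):
        # Two categories only, but every person answers identically.
        values = np.tile([2.0], (4, 3))
        with pytest.raises(CalibrationError):
            mv.msd_calibrate(mv.RatingMatrix(values, 4))

    def test_calibration_is_deterministic(self):
        matrix, _ = simulated(17, n=80)
        a = mv.msd_calibrate(matrix)
        b = mv.msd_calibrate(matrix)
        np.testing.assert_array_equal(a.item_measures, b.item_measures)
        np.testing.assert_array_equal(a.thresholds, b.thresholds)


class TestThresholds:
    def test_balanced_single_threshold_is_zero(self):
        values = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        matrix = mv.RatingMatrix(values, 1)
        tau, se = estimate_thresholds(matrix, np.zeros(2), np.zeros(4))
        assert tau[0] == pytest.approx(0.0, abs=1e-8)
        assert se[0] > 0

    def test_recovery_with_true_anchors(self):
        tau_true = np.array([-2.4, -0.8, 0.6, 2.2])
        config = mv.SimulationConfig(seed=23, n_persons=2000, thresholds=tau_true)
        matrix, theta = mv.simulate_responses(config, return_truth=True)
        b_true = config.item_measures - config.item_measures.mean()
        tau, se = estimate_thresholds(matrix, b_true, theta)
        assert np.all(np.abs(tau - tau_true) < 0.1)
        assert np.all(se > 0)

    def test_degenerate_cut_warns_and_returns_nan(self):
        # Category 2 unused and no response reaches cut 2.
        values = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 0.0]])
        matrix = mv.RatingMatrix(values, 2)
        with pytest.warns(UserWarning):
            tau, _ = estimate_thresholds(matrix, np.zeros(2), np.zeros(3))
        assert np.isnan(tau[1])


class TestStandardErrors:
    def test_sqrt_n_shrinkage(self):
        medians = {}
        for n in (400, 800):
            matrix, _ = simulated(21, n=n)
            medians[n] = np.nanmedian(mv.msd_calibrate(matrix).item_se)
        ratio = medians[800] / medians[400]
        assert ratio == pytest.approx(1.0 / np.sqrt(2.0), rel=0.15)

    def test_partial_response_inflates_person_se(self, bank_25c):
        full = np.full(30, 2.0)
        half = full.copy()
        half[15:] = np.nan
        assert (
            mv.score_person(half, bank_25c).se > mv.score_person(full, bank_25c).se
        )

    def test_item_precision_far_exceeds_person_precision(self):
        """With thousands of persons rating 30 items, person measure
        errors are several times the item measure errors."""
        matrix, _ = simulated(37, n=3342)
        cal = mv.msd_calibrate(matrix)
        ratio = np.nanmedian(cal.person_se) / np.nanmedian(cal.item_se)
        assert ratio > 5.0
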