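"""Dichotomous Rasch estimation against closed forms and grid oracles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import msdvfq as mv
from msdvfq.exceptions import (
    CalibrationError,
    DataValidationError,
    NoDataError,
)

from oracles import grid_jmle, scan_binary_score_equation


class TestFitDichotomous:
    def test_symmetric_2x2_centers_at_zero(self):
        fit = mv.fit_dichotomous(np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(fit.item_difficulties, 0.0, atol=1e-8)
        np.testing.assert_allclose(fit.person_abilities, 0.0, atol=1e-8)

    def test_extreme_person_is_reported_missing(self):
        X = np.array([[1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
        fit = mv.fit_dichotomous(X)
        assert np.isnan(fit.person_abilities[0])
        assert np.isfinite(fit.person_abilities[1:]).all()
        assert not fit.estimable_persons[0]

    def test_centering_of_estimable_items(self):
        rng = np.random.default_rng(4)
        X = (rng.uniform(size=(25, 6)) < 0.5).astype(float)
        fit = mv.fit_dichotomous(X)
        assert abs(np.nanmean(fit.item_difficulties)) < 1e-9

    def test_matches_grid_oracle_on_3x2(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        fit = mv.fit_dichotomous(X, tol=1e-7)
        theta_o, b_o = grid_jmle(X)
        np.testing.assert_allclose(fit.item_difficulties, b_o, atol=1e-4)
        np.testing.assert_allclose(fit.person_abilities, theta_o, atol=1e-4)

    def test_flip_symmetry_negates_estimates(self):
        rng = np.random.default_rng(12)
        X = (rng.uniform(size=(30, 5)) < 0.6).astype(float)
        fit = mv.fit_dichotomous(X)
        flipped = mv.fit_dichotomous(1.0 - X)
        np.testing.assert_allclose(
            fit.item_difficulties, -flipped.item_difficulties, atol=1e-6
        )
        np.testing.assert_allclose(
            fit.person_abilities, -flipped.person_abilities, atol=1e-6
        )

    def test_missing_entries_are_tolerated(self):
        X = np.array(
            [[1.0, 0.0, np.nan], [0.0, 1.0, 1.0], [1.0, np.nan, 0.0], [0.0, 1.0, 0.0]]
        )
        fit = mv.fit_dichotomous(X)
        assert np.isfinite(fit.item_difficulties).all()

    def test_empty_and_all_extreme_inputs_fail(self):
        with pytest.raises(DataValidationError):
            mv.fit_dichotomous(np.empty((0, 0)))
        with pytest.raises(CalibrationError):
            mv.fit_dichotomous(np.ones((3, 3)))

    def test_non_binary_entries_rejected(self):
        with pytest.raises(DataValidationError):
            mv.fit_dichotomous(np.array([[2.0, 0.0], [0.0, 1.0]]))

    def test_anchored_fit_estimates_persons_only(self):
        anchors = np.array([-0.5, 0.0, 0.5])
        X = np.array([[1.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
        fit = mv.fit_dichotomous(X, anchors=anchors)
        assert fit.anchored
        np.testing.assert_array_equal(fit.item_difficulties, anchors)
        for row, theta in zip(X, fit.person_abilities):
            ref = mv.person_mle_dichotomous(row, anchors)
            assert theta == pytest.approx(ref.measure, abs=1e-5)


class TestPersonMLE:
    def test_symmetric_score_equation(self):
        est = mv.person_mle_dichotomous(np.array([1.0, 0.0]), np.array([-1.0, 1.0]))
        assert est.measure == pytest.approx(0.0, abs=1e-8)
        assert est.status is mv.ScoringStatus.ESTIMATED

    def test_one_of_three_matches_closed_form_and_scan(self):
        est = mv.person_mle_dichotomous(np.array([1.0, 0.0, 0.0]), np.zeros(3))
        assert est.measure == pytest.approx(np.log(0.5), abs=1e-6)
        scanned = scan_binary_score_equation(np.zeros(3), 1.0)
        assert est.measure == pytest.approx(scanned, abs=1e-4)

    def test_all_correct_is_ceiling(self):
        est = mv.person_mle_dichotomous(np.array([1.0, 1.0]), np.zeros(2))
        assert est.status is mv.ScoringStatus.CEILING
        assert np.isnan(est.measure)

    def test_all_wrong_is_floor(self):
        est = mv.person_mle_dichotomous(np.array([0.0, 0.0]), np.zeros(2))
        assert est.status is mv.ScoringStatus.FLOOR

    def test_all_missing_raises(self):
        with pytest.raises(NoDataError):
            mv.person_mle_dichotomous(np.array([np.nan, np.nan]), np.zeros(2))

    def test_se_is_inverse_root_information(self):
        b = np.array([-0.3, 0.2, 0.8])
        est = mv.person_mle_dichotomous(np.array([1.0, 1.0, 0.0]), b)
        p = 1.0 / (1.0 + np.exp(-(est.measure - b)))
        assert est.se == pytest.approx(1.0 / np.sqrt(np.sum(p * (1 - p))), rel=1e-6)

    @settings(derandomize=True, max_examples=30)
    @given(
        shift=st.floats(-3.0, 3.0),
        pattern=st.lists(st.booleans(), min_size=3, max_size=8),
    )
    def test_translation_invariance(self, shift, pattern):
        """Adding c to all anchored difficulties shifts the estimate by c."""
        x = np.array(pattern, dtype=float)
        if x.sum() in (0, len(x)):
            return
        b = np.linspace(-1, 1, len(x))
        base = mv.person_mle_dichotomous(x, b, tol=1e-9)
        shifted = mv.person_mle_dichotomous(x, b + shift, tol=1e-9)
        assert shifted.measure - base.measure == pytest.approx(shift, abs=1e-6)

    def test_monotone_in_raw_score(self):
        b = np.linspace(-1.5, 1.5, 6)
        measures = []
        for score in range(1, 6):
            x = np.zeros(6)
            x[:score] = 1.0
            measures.append(mv.person_mle_dichotomous(x, b).measure)
        assert np.all(np.diff(measures) > 0)
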