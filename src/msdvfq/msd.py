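"""Polytomous Rasch calibration by the method of successive dichotomizations.

For ratings in ordered categories 0..M the method fits the dichotomous
Rasch model to each of the M cuts of the response scale: responses are
recoded to ``1`` when at or above the cut and ``0`` below it.  Item and
person measures are the averages of the per-cut estimates (each cut's fit
centered to mean item difficulty zero before averaging), and the M rating
category thresholds are then estimated one at a time by anchored
maximum likelihood: with item and person measures fixed, the cut-k
dichotomized likelihood is maximized over the single scalar tau_k.

Because the proportion of responses at or above cut k decreases strictly
in k whenever every category is used, the anchored threshold estimates
come out in increasing order - the property that distinguishes this
approach from partial-credit-style fits, which can return disordered
thresholds.

The model for a single response implied by this construction is the
cumulative-logit ("graded") form

    P(X_ni >= k) = sigma(theta_n - b_i - tau_k),      k = 1..M,

with one shared threshold vector per instrument (rating-scale
convention), and it is the model under which simulated data are generated
for parameter-recovery checks.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import RatingMatrix
from .exceptions import CalibrationError, DataValidationError
from .rasch import MAX_LOGIT, MAX_STEP, fit_dichotomous

__all__ = [
    "MSDCalibration",
    "dichotomize",
    "msd_calibrate",
    "estimate_thresholds",
    "standard_errors",
]

logger = logging.getLogger(__name__)


@dataclass
class MSDCalibration:
    """A calibrated instrument: item measures, shared ordered thresholds,
    and (optionally) the calibration sample's person measures.

    Unanchored calibrations are centered so estimable item measures have
    mean zero; person measures are on the same origin.  Inestimable
    parameters are NaN.
    """

    item_ids: list[str]
    item_measures: np.ndarray
    item_se: np.ndarray
    thresholds: np.ndarray
    threshold_se: np.ndarray
    m: int
    person_ids: Optional[list[str]] = None
    person_measures: Optional[np.ndarray] = None
    person_se: Optional[np.ndarray] = None
    centering: str = "items_mean_zero"
    converged: bool = True
    item_support: Optional[np.ndarray] = None
    person_support: Optional[np.ndarray] = None

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def item_index(self, item_ids: Sequence[str]) -> np.ndarray:
        lookup = {iid: j for j, iid in enumerate(self.item_ids)}
        missing = [i for i in item_ids if i not in lookup]
        if missing:
            raise DataValidationError(f"unknown item ids: {missing}")
        return np.array([lookup[i] for i in item_ids], dtype=int)

    def items_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "measure": self.item_measures,
                "se": self.item_se,
            }
        )

    def thresholds_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold_index": np.arange(1, self.m + 1),
                "estimate": self.thresholds,
                "se": self.threshold_se,
            }
        )

    def persons_frame(self) -> pd.DataFrame:
        if self.person_measures is None:
            raise DataValidationError("calibration carries no person measures")
        return pd.DataFrame(
            {
                "person_id": self.person_ids,
                "measure": self.person_measures,
                "se": self.person_se,
            }
        )


def dichotomize(matrix: RatingMatrix, k: int) -> np.ndarray:
    """Binary recode of a rating matrix at cut ``k``: 1 iff response >= k.

    Missing responses stay missing.  ``k`` runs from 1 to M, giving the M
    successive dichotomizations {0} vs {1..M}, {0,1} vs {2..M}, ...
    """
    if not 1 <= k <= matrix.m:
        raise DataValidationError(f"cut index {k} outside 1..{matrix.m}")
    out = np.where(matrix.observed, (matrix.values >= k).astype(float), np.nan)
    return out


def estimate_thresholds(
    matrix: RatingMatrix,
    item_measures: np.ndarray,
    person_measures: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Anchored single-parameter MLE of each rating category threshold.

    For cut ``k`` the dichotomized responses follow a dichotomous Rasch
    model with logit ``theta_n - b_i - tau_k``; with the measures anchored
    the log-likelihood is concave in the scalar ``tau_k`` and Newton
    iteration solves the score equation

        sum_ni sigma(theta_n - b_i - tau_k) = sum_ni x_ni(k).

    The standard error is the inverse square root of the scalar Fisher
    information.  Cuts with all-0 or all-1 observed responses have no
    finite estimate and come back NaN with a warning.
    """
    b = np.asarray(item_measures, dtype=float)
    theta = np.asarray(person_measures, dtype=float)
    usable = (
        matrix.observed
        & np.isfinite(theta)[:, None]
        & np.isfinite(b)[None, :]
    )
    eta = theta[:, None] - b[None, :]
    thresholds = np.full(matrix.m, np.nan)
    threshold_se = np.full(matrix.m, np.nan)
    for k in range(1, matrix.m + 1):
        Xk = dichotomize(matrix, k)
        mask = usable & np.isfinite(Xk)
        n_obs = mask.sum()
        if n_obs == 0:
            warnings.warn(f"threshold {k}: no usable responses", stacklevel=2)
            continue
        s = np.where(mask, np.nan_to_num(Xk), 0.0).sum()
        if s == 0 or s == n_obs:
            warnings.warn(
                f"threshold {k}: dichotomized responses are all "
                f"{'1' if s else '0'}; estimate is not finite",
                stacklevel=2,
            )
            continue
        tau = 0.0
        for _ in range(max_iter):
            P = np.where(mask, expit(eta - tau), 0.0)
            info = (P * (1.0 - P)).sum()
            step = float(np.clip((P.sum() - s) / info, -MAX_STEP, MAX_STEP))
            tau = float(np.clip(tau + step, -MAX_LOGIT, MAX_LOGIT))
            if abs(step) < tol:
                break
        P = np.where(mask, expit(eta - tau), 0.0)
        info = (P * (1.0 - P)).sum()
        thresholds[k - 1] = tau
        threshold_se[k - 1] = 1.0 / np.sqrt(info)
    return thresholds, threshold_se


def standard_errors(
    matrix: RatingMatrix, calibration: MSDCalibration
) -> tuple[np.ndarray, np.ndarray]:
    """Item and person standard errors from the composite-dichotomization
    information.

    Each answered response contributes, for every cut k, a Bernoulli
    information term p(1-p) evaluated at ``theta_n - b_i - tau_k``; the
    standard error of a parameter is the inverse square root of the sum of
    its terms.  Errors therefore shrink as 1/sqrt(number of responses):
    item precision grows with the person sample while person precision is
    limited by the (much smaller) number of items answered.
    """
    b = calibration.item_measures
    theta = calibration.person_measures
    tau = calibration.thresholds
    if theta is None:
        raise DataValidationError("calibration carries no person measures")
    usable = (
        matrix.observed & np.isfinite(theta)[:, None] & np.isfinite(b)[None, :]
    )
    eta = theta[:, None] - b[None, :]
    info = np.zeros_like(eta)
    for t in tau[np.isfinite(tau)]:
        P = expit(eta - t)
        info += P * (1.0 - P)
    info = np.where(usable, info, 0.0)
    info_items = info.sum(axis=0)
    info_persons = info.sum(axis=1)
    with np.errstate(divide="ignore"):
        item_se = np.where(
            np.isfinite(b) & (info_items > 0), 1.0 / np.sqrt(info_items), np.nan
        )
        person_se = np.where(
            np.isfinite(theta) & (info_persons > 0),
            1.0 / np.sqrt(info_persons),
            np.nan,
        )
    return item_se, person_se


def _composite_theta(
    matrix: RatingMatrix,
    item_measures: np.ndarray,
    thresholds: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """Vectorised composite score-equation person estimates.

    Solves, for every person, sum_i sum_k sigma(theta - b_i - tau_k) =
    raw score over answered items with finite measures.  All-bottom and
    all-top patterns (and empty rows) come back NaN.
    """
    b = np.asarray(item_measures, dtype=float)
    tau = np.asarray(thresholds, dtype=float)
    answered = matrix.observed & np.isfinite(b)[None, :]
    x = np.where(answered, np.nan_to_num(matrix.values), 0.0)
    raw = x.sum(axis=1)
    max_raw = answered.sum(axis=1) * matrix.m
    estimable = (max_raw > 0) & (raw > 0) & (raw < max_raw)
    theta = np.zeros(matrix.n_persons)
    for _ in range(max_iter):
        eta = theta[:, None, None] - b[None, :, None] - tau[None, None, :]
        P = np.where(answered[:, :, None], expit(eta), 0.0)
        expected = P.sum(axis=(1, 2))
        info = (P * (1.0 - P)).sum(axis=(1, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(estimable, (raw - expected) / info, 0.0)
        step = np.clip(step, -MAX_STEP, MAX_STEP)
        theta = np.clip(theta + step, -MAX_LOGIT, MAX_LOGIT)
        if np.max(np.abs(step), initial=0.0) < tol:
            break
    return np.where(estimable, theta, np.nan)


def msd_calibrate(
    matrix: RatingMatrix,
    *,
    tol: float = 1e-5,
    max_iter: int = 1000,
    bias_correction: bool = False,
) -> MSDCalibration:
    """Calibrate a polytomous rating matrix by successive dichotomizations.

    Fits the dichotomous Rasch model at each of the M cuts; item measures
    are the averages of the per-cut estimates over the cuts in which the
    item was estimable, re-centered to mean zero.  Thresholds and person
    measures are then iterated to a self-consistent pair: each threshold
    is the anchored single-parameter MLE given the current measures, and
    person measures solve the composite score equation

        sum_i sum_k sigma(theta_n - b_i - tau_k) = raw score,

    the same equation the anchored scorer uses, so re-scoring the
    calibration sample against the produced calibration reproduces its
    person measures.  The iteration is seeded with the plain per-cut
    person averages; those averages alone would carry a selection offset
    for persons estimable in only a subset of cuts (a cut's centered fit
    expresses abilities relative to that cut's threshold), which the
    composite re-estimate removes.

    Note the gauge freedom of the model: adding a constant to every
    threshold and every person measure leaves all response probabilities
    unchanged, so the threshold origin reported here is the one inherited
    from the per-cut averages (approximately mean-centered thresholds).

    Persons with all-bottom or all-top response patterns, and items
    estimable in no cut, come back NaN.

    Raises
    ------
    CalibrationError
        If no cut admits any estimable item.
    """
    if matrix.n_items < 2 or matrix.n_persons < 2:
        raise DataValidationError("calibration needs >= 2 persons and >= 2 items")

    n_p, n_i = matrix.n_persons, matrix.n_items
    b_by_cut = np.full((matrix.m, n_i), np.nan)
    theta_by_cut = np.full((matrix.m, n_p), np.nan)
    converged = True
    any_fit = False
    for k in range(1, matrix.m + 1):
        Xk = dichotomize(matrix, k)
        try:
            fit = fit_dichotomous(
                Xk, tol=tol, max_iter=max_iter, bias_correction=bias_correction
            )
        except CalibrationError:
            logger.info("cut %d: no estimable parameters, skipped", k)
            continue
        any_fit = True
        converged &= fit.converged
        b_by_cut[k - 1] = fit.item_difficulties
        theta_by_cut[k - 1] = fit.person_abilities
    if not any_fit:
        raise CalibrationError("no dichotomization is estimable")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        b = np.nanmean(b_by_cut, axis=0)
        theta = np.nanmean(theta_by_cut, axis=0)
    item_support = np.isfinite(b_by_cut).sum(axis=0)
    person_support = np.isfinite(theta_by_cut).sum(axis=0)

    center = np.nanmean(b)
    b = b - center
    theta = theta - center

    # Alternate anchored threshold MLE and composite person re-estimation
    # until the thresholds stabilise; finish with a person update so the
    # reported measures solve the score equation at the reported
    # thresholds exactly.
    thresholds = threshold_se = None
    for _ in range(25):
        new_thresholds, threshold_se = estimate_thresholds(matrix, b, theta)
        if not np.all(np.isfinite(new_thresholds)):
            # Degenerate data (an unused category): keep the per-cut
            # averaged person measures rather than a partial composite.
            thresholds = new_thresholds
            break
        done = thresholds is not None and np.nanmax(
            np.abs(new_thresholds - thresholds)
        ) < 1e-7
        thresholds = new_thresholds
        theta = _composite_theta(matrix, b, thresholds)
        if done:
            break

    n_dropped = int(np.sum(~np.isfinite(theta)))
    if n_dropped:
        logger.info(
            "%d of %d persons with inestimable (extreme) measures", n_dropped, n_p
        )
    calibration = MSDCalibration(
        item_ids=list(matrix.item_ids),
        item_measures=b,
        item_se=np.full(n_i, np.nan),
        thresholds=thresholds,
        threshold_se=threshold_se,
        m=matrix.m,
        person_ids=list(matrix.person_ids),
        person_measures=theta,
        person_se=np.full(n_p, np.nan),
        converged=converged,
        item_support=item_support,
        person_support=person_support,
    )
    item_se, person_se = standard_errors(matrix, calibration)
    calibration.item_se = item_se
    calibration.person_se = person_se
    return calibration
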