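"""Dichotomous Rasch model estimation by joint maximum likelihood.

The dichotomous Rasch model gives the probability that person ``n`` passes
item ``i`` as

    P(x_ni = 1) = exp(theta_n - b_i) / (1 + exp(theta_n - b_i)),

with person ability ``theta_n`` and item difficulty ``b_i`` on a common
logit scale.  This module estimates both parameter sets jointly (JMLE) by
alternating damped Newton-Raphson steps on the person and item score
equations, or estimates persons alone against anchored (fixed) item
difficulties.

The scale of an unanchored fit is fixed by centering: estimable item
difficulties are constrained to mean zero, and person abilities are
expressed on that same origin.

Persons or items whose observed responses are all 0 or all 1 (extreme
scores) have no finite maximum-likelihood estimate.  They are excluded
from estimation but retained in the output arrays as NaN so that indexing
stays stable for callers that average several fits.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

from .containers import PersonEstimate, ScoringStatus
from .exceptions import CalibrationError, DataValidationError, NoDataError

__all__ = ["DichotomousFit", "fit_dichotomous", "person_mle_dichotomous"]

#: Hard bound on parameter magnitudes during iteration; quasi-extreme
#: response patterns can otherwise push estimates toward infinity.
MAX_LOGIT = 20.0

#: Largest Newton step accepted in a single iteration (step damping).
MAX_STEP = 1.0


@dataclass
class DichotomousFit:
    """Result of a dichotomous Rasch fit.

    Estimates are NaN for persons/items with extreme scores (no finite
    MLE).  For anchored fits the item difficulties echo the anchors and
    item standard errors are NaN (not estimated).
    """

    item_difficulties: np.ndarray
    person_abilities: np.ndarray
    item_se: np.ndarray
    person_se: np.ndarray
    converged: bool
    iterations: int
    estimable_items: np.ndarray
    estimable_persons: np.ndarray
    anchored: bool = False


def _validate_binary(responses: np.ndarray) -> np.ndarray:
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2 or X.size == 0:
        raise DataValidationError("binary response matrix must be 2-d and non-empty")
    obs = np.isfinite(X)
    vals = X[obs]
    if vals.size == 0:
        raise DataValidationError("binary response matrix has no observed entries")
    if not np.all((vals == 0.0) | (vals == 1.0)):
        raise DataValidationError("non-missing entries must be 0 or 1")
    return X

def _prune_extremes(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively flag persons/items whose retained responses are extreme.

    Dropping an extreme person can render an item extreme in turn, so the
    scan repeats until stable.
    """
    obs = np.isfinite(X)
    filled = np.where(obs, X, 0.0)
    keep_p = np.ones(X.shape[0], dtype=bool)
    keep_i = np.ones(X.shape[1], dtype=bool)
    while True:
        mask = obs & keep_p[:, None] & keep_i[None, :]
        n_row = mask.sum(axis=1)
        s_row = np.where(mask, filled, 0.0).sum(axis=1)
        bad_p = keep_p & ((n_row == 0) | (s_row == 0) | (s_row == n_row))
        if bad_p.any():
            keep_p &= ~bad_p
            continue
        n_col = mask.sum(axis=0)
        s_col = np.where(mask, filled, 0.0).sum(axis=0)
        bad_i = keep_i & ((n_col == 0) | (s_col == 0) | (s_col == n_col))
        if bad_i.any():
            keep_i &= ~bad_i
            continue
        break
    return keep_p, keep_i


def _person_newton(
    X: np.ndarray,
    difficulties: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Newton solve of the person score equations with all item
    difficulties fixed.  Rows with extreme scores come back NaN."""
    obs = np.isfinite(X) & np.isfinite(difficulties)[None, :]
    r = np.where(obs, np.nan_to_num(X), 0.0).sum(axis=1)
    n = obs.sum(axis=1)
    estimable = (n > 0) & (r > 0) & (r < n)
    theta = np.zeros(X.shape[0])
    for _ in range(max_iter):
        P = expit(theta[:, None] - difficulties[None, :])
        P = np.where(obs, P, 0.0)
        expected = P.sum(axis=1)
        info = (P * (1.0 - P)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(estimable, (r - expected) / info, 0.0)
        step = np.clip(step, -MAX_STEP, MAX_STEP)
        theta = np.clip(theta + step, -MAX_LOGIT, MAX_LOGIT)
        if np.max(np.abs(step), initial=0.0) < tol:
            break
    P = np.where(obs, expit(theta[:, None] - difficulties[None, :]), 0.0)
    info = (P * (1.0 - P)).sum(axis=1)
    with np.errstate(divide="ignore"):
        se = np.where(estimable & (info > 0), 1.0 / np.sqrt(info), np.nan)
    theta = np.where(estimable, theta, np.nan)
    return theta, se


def fit_dichotomous(
    responses: np.ndarray,
    anchors: Optional[np.ndarray] = None,
    *,
    tol: float = 1e-5,
    max_iter: int = 1000,
    bias_correction: bool = False,
) -> DichotomousFit:
    """Fit the dichotomous Rasch model to a binary person x item matrix.

    Parameters
    ----------
    responses
        Persons x items array with entries in {0, 1, NaN}.
    anchors
        If given, a full vector of fixed item difficulties: only person
        abilities are estimated (anchored scoring).  Anchoring a strict
        subset of items is not supported.
    tol
        Convergence criterion: largest absolute parameter change in one
        alternating sweep, in logits.
    max_iter
        Iteration cap for the alternating Newton scheme.
    bias_correction
        Apply the classical (L-1)/L shrinkage to unanchored item
        difficulties (L = number of estimable items), then re-estimate
        persons against the corrected difficulties.  Off by default: final
        polytomous measures are averages across dichotomizations and the
        raw JMLE estimates keep that average on a consistent scale.

    Returns
    -------
    DichotomousFit
        Centered estimates (unanchored fits only) with standard errors from
        the Fisher information at the estimates.
    """
    X = _validate_binary(responses)
    n_persons, n_items = X.shape

    if anchors is not None:
        anchors = np.asarray(anchors, dtype=float)
        if anchors.shape != (n_items,):
            raise DataValidationError(
                "anchors must provide one difficulty per item"
            )
        if not np.all(np.isfinite(anchors)):
            raise DataValidationError("anchored difficulties must be finite")
        theta, person_se = _person_newton(X, anchors, tol, max_iter)
        return DichotomousFit(
            item_difficulties=anchors.copy(),
            person_abilities=theta,
            item_se=np.full(n_items, np.nan),
            person_se=person_se,
            converged=True,
            iterations=0,
            estimable_items=np.ones(n_items, dtype=bool),
            estimable_persons=np.isfinite(theta),
            anchored=True,
        )

    keep_p, keep_i = _prune_extremes(X)
    if not keep_i.any():
        raise CalibrationError(
            "no estimable item: every column has an extreme score"
        )
    if not keep_p.any():
        raise CalibrationError(
            "no estimable person: every row has an extreme score"
        )

    sub = X[np.ix_(keep_p, keep_i)]
    obs = np.isfinite(sub)
    filled = np.where(obs, sub, 0.0)
    r = filled.sum(axis=1)
    n_ans = obs.sum(axis=1)
    s = filled.sum(axis=0)
    n_obs_i = obs.sum(axis=0)

    # Logit-of-proportion starting values speed convergence considerably
    # relative to a zero start, particularly for skewed dichotomizations.
    theta = np.log((r + 0.5) / (n_ans - r + 0.5))
    b = np.log((n_obs_i - s + 0.5) / (s + 0.5))
    b -= b.mean()

    converged = False
    iterations = 0
    for iteration in range(1, max_iter + 1):
        iterations = iteration
        # Item step with persons fixed.
        P = np.where(obs, expit(theta[:, None] - b[None, :]), 0.0)
        info_i = (P * (1.0 - P)).sum(axis=0)
        step_i = np.clip((P.sum(axis=0) - s) / info_i, -MAX_STEP, MAX_STEP)
        b = np.clip(b + step_i, -MAX_LOGIT, MAX_LOGIT)
        # Person step with items fixed.
        P = np.where(obs, expit(theta[:, None] - b[None, :]), 0.0)
        info_p = (P * (1.0 - P)).sum(axis=1)
        step_p = np.clip((r - P.sum(axis=1)) / info_p, -MAX_STEP, MAX_STEP)
        theta = np.clip(theta + step_p, -MAX_LOGIT, MAX_LOGIT)
        # Re-fix the origin each sweep.
        center = b.mean()
        b -= center
        theta -= center
        if max(np.max(np.abs(step_i)), np.max(np.abs(step_p))) < tol:
            converged = True
            break

    if bias_correction and keep_i.sum() > 1:
        L = keep_i.sum()
        b *= (L - 1.0) / L
        theta, _ = _person_newton(sub, b, tol, max_iter)

    P = np.where(obs, expit(theta[:, None] - b[None, :]), 0.0)
    W = P * (1.0 - P)
    with np.errstate(divide="ignore"):
        item_se_sub = 1.0 / np.sqrt(W.sum(axis=0))
        person_se_sub = 1.0 / np.sqrt(W.sum(axis=1))

    item_difficulties = np.full(n_items, np.nan)
    person_abilities = np.full(n_persons, np.nan)
    item_se = np.full(n_items, np.nan)
    person_se = np.full(n_persons, np.nan)
    item_difficulties[keep_i] = b
    person_abilities[keep_p] = theta
    item_se[keep_i] = item_se_sub
    person_se[keep_p] = person_se_sub
    return DichotomousFit(
        item_difficulties=item_difficulties,
        person_abilities=person_abilities,
        item_se=item_se,
        person_se=person_se,
        converged=converged,
        iterations=iterations,
        estimable_items=keep_i,
        estimable_persons=keep_p,
    )


def person_mle_dichotomous(
    responses: np.ndarray,
    anchored_difficulties: np.ndarray,
    *,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> PersonEstimate:
    """Maximum-likelihood person measure for one binary response vector
    against anchored item difficulties.

    The estimate solves the score equation

        sum_i sigma(theta - b_i) = observed score

    over answered items; its standard error is the inverse square root of
    the Fisher information sum_i p_i (1 - p_i).  All-0 and all-1 patterns
    have no finite solution and come back with ``floor``/``ceiling``
    status and a missing measure.
    """
    x = np.asarray(responses, dtype=float)
    b = np.asarray(anchored_difficulties, dtype=float)
    if x.shape != b.shape or x.ndim != 1:
        raise DataValidationError(
            "responses and anchored difficulties must be matching vectors"
        )
    answered = np.isfinite(x) & np.isfinite(b)
    if not answered.any():
        raise NoDataError("no answered items")
    vals = x[answered]
    if not np.all((vals == 0.0) | (vals == 1.0)):
        raise DataValidationError("non-missing responses must be 0 or 1")
    raw = int(vals.sum())
    n = int(answered.sum())
    if raw == 0 or raw == n:
        status = ScoringStatus.FLOOR if raw == 0 else ScoringStatus.CEILING
        return PersonEstimate(
            measure=np.nan,
            se=np.nan,
            raw_score=raw,
            n_answered=n,
            status=status,
        )
    bk = b[answered]
    theta = 0.0
    for _ in range(max_iter):
        p = expit(theta - bk)
        info = np.sum(p * (1.0 - p))
        step = float(np.clip((raw - p.sum()) / info, -MAX_STEP, MAX_STEP))
        theta = float(np.clip(theta + step, -MAX_LOGIT, MAX_LOGIT))
        if abs(step) < tol:
            break
    p = expit(theta - bk)
    se = float(1.0 / np.sqrt(np.sum(p * (1.0 - p))))
    return PersonEstimate(
        measure=theta,
        se=se,
        raw_score=raw,
        n_answered=n,
        status=ScoringStatus.ESTIMATED,
    )
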