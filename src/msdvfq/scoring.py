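"""Anchored person-measure estimation against a fixed item bank.

Scoring treats the bank's item measures ``b_i`` and shared thresholds
``tau_k`` as known constants and maximizes the composite-dichotomization
likelihood for one respondent.  The resulting score equation is

    sum_{i answered} sum_{k=1..M} sigma(theta - b_i - tau_k) = raw score,

where the raw score is the total number of cuts passed, i.e. simply the
sum of the responses over answered items.  The left side is strictly
increasing in theta, so the measure is the unique root; the standard
error is the inverse square root of the Fisher information
``sum sigma (1 - sigma)`` at the estimate.

All-top and all-bottom patterns have no finite root.  They are returned
with ``ceiling``/``floor`` status, a missing measure, and the bounds of
the estimable range for the answered subset (the solutions one raw-score
unit inside each extreme), so users know the direction and the smallest
measure consistent with the pattern.
"""
from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .containers import MeasureBounds, PersonEstimate, RatingMatrix, ScoringStatus
from .exceptions import DataValidationError
from .msd import MSDCalibration
from .rasch import MAX_LOGIT, MAX_STEP

__all__ = ["score_person", "score_matrix", "measure_bounds", "mcid"]


def _score_curve(theta: float, b: np.ndarray, tau: np.ndarray) -> float:
    """Expected raw score sum_i sum_k sigma(theta - b_i - tau_k)."""
    return float(expit(theta - b[:, None] - tau[None, :]).sum())


def _solve_score_equation(
    b: np.ndarray, tau: np.ndarray, target: float, tol: float = 1e-6
) -> float:
    """Root of the score equation by damped Newton with a bracketed
    fallback on [-MAX_LOGIT, MAX_LOGIT]."""
    theta = 0.0
    for _ in range(100):
        eta = theta - b[:, None] - tau[None, :]
        P = expit(eta)
        info = float((P * (1.0 - P)).sum())
        if info <= 0:
            break
        step = float(np.clip((target - P.sum()) / info, -MAX_STEP, MAX_STEP))
        theta = float(np.clip(theta + step, -MAX_LOGIT, MAX_LOGIT))
        if abs(step) < tol:
            return theta
    # Newton stalled (e.g. target very close to an extreme): bisect.
    f = lambda t: _score_curve(t, b, tau) - target
    lo, hi = -MAX_LOGIT, MAX_LOGIT
    if f(lo) > 0 or f(hi) < 0:
        raise DataValidationError("raw score outside the estimable range")
    return float(brentq(f, lo, hi, xtol=tol))


def _bank_arrays(bank: MSDCalibration) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(bank.item_measures, dtype=float)
    tau = np.asarray(bank.thresholds, dtype=float)
    if not np.all(np.isfinite(tau)):
        raise DataValidationError("bank thresholds must be finite")
    return b, tau


def measure_bounds(
    bank: MSDCalibration, answered: Optional[Sequence[str]] = None
) -> MeasureBounds:
    """Range of person measures estimable from an answered-item subset.

    ``max_measure`` solves the score equation at one raw-score unit below
    the maximum (n_answered * M - 1) and ``min_measure`` at raw score 1 -
    the most extreme scores that still admit a finite MLE.
    """
    b, tau = _bank_arrays(bank)
    if answered is None:
        answered = list(bank.item_ids)
    if len(answered) == 0:
        raise DataValidationError("empty answered-item subset")
    idx = bank.item_index(answered)
    bs = b[idx]
    if not np.all(np.isfinite(bs)):
        raise DataValidationError("answered subset includes inestimable items")
    max_raw = len(bs) * bank.m
    return MeasureBounds(
        min_measure=_solve_score_equation(bs, tau, 1.0),
        max_measure=_solve_score_equation(bs, tau, max_raw - 1.0),
        item_subset=tuple(answered),
    )


def score_person(
    responses: Union[np.ndarray, Sequence[float]],
    bank: MSDCalibration,
    *,
    tol: float = 1e-6,
) -> PersonEstimate:
    """Estimate one person's measure against an anchored item bank.

    ``responses`` must align with ``bank.item_ids`` (length and order);
    entries are integer categories 0..M or NaN for missing.  Items the
    respondent skipped simply drop out of the score equation - the measure
    stays on the bank's scale and only the standard error grows.
    """
    x = np.asarray(responses, dtype=float)
    if x.ndim != 1 or x.shape[0] != bank.n_items:
        raise DataValidationError(
            f"expected {bank.n_items} responses, got shape {x.shape}"
        )
    b, tau = _bank_arrays(bank)
    answered = np.isfinite(x) & np.isfinite(b)
    n_answered = int(answered.sum())
    if n_answered == 0:
        return PersonEstimate(
            measure=np.nan,
            se=np.nan,
            raw_score=0,
            n_answered=0,
            status=ScoringStatus.NO_DATA,
        )
    vals = x[answered]
    if np.any((vals < 0) | (vals > bank.m) | (vals != np.round(vals))):
        raise DataValidationError(f"responses must be integers in 0..{bank.m}")
    raw = int(vals.sum())
    max_raw = n_answered * bank.m
    answered_ids = [iid for iid, a in zip(bank.item_ids, answered) if a]
    if raw == 0 or raw == max_raw:
        status = ScoringStatus.FLOOR if raw == 0 else ScoringStatus.CEILING
        return PersonEstimate(
            measure=np.nan,
            se=np.nan,
            raw_score=raw,
            n_answered=n_answered,
            status=status,
            bounds=measure_bounds(bank, answered_ids),
        )
    bs = b[answered]
    theta = _solve_score_equation(bs, tau, float(raw), tol)
    P = expit(theta - bs[:, None] - tau[None, :])
    se = float(1.0 / np.sqrt((P * (1.0 - P)).sum()))
    return PersonEstimate(
        measure=theta,
        se=se,
        raw_score=raw,
        n_answered=n_answered,
        status=ScoringStatus.ESTIMATED,
        bounds=measure_bounds(bank, answered_ids),
    )


def score_matrix(matrix: RatingMatrix, bank: MSDCalibration) -> pd.DataFrame:
    """Score every row of a rating matrix against a bank.

    Returns one row per person with columns person_id, measure, se,
    raw_score, n_answered, status, min_measure, max_measure.
    """
    if list(matrix.item_ids) != list(bank.item_ids):
        matrix = matrix.subset_items(bank.item_ids)
    if matrix.m != bank.m:
        raise DataValidationError(
            f"matrix has categories 0..{matrix.m}, bank expects 0..{bank.m}"
        )
    rows = []
    for pid, resp in zip(matrix.person_ids, matrix.values):
        est = score_person(resp, bank)
        rows.append(
            {
                "person_id": pid,
                "measure": est.measure,
                "se": est.se,
                "raw_score": est.raw_score,
                "n_answered": est.n_answered,
                "status": est.status.value,
                "min_measure": est.bounds.min_measure if est.bounds else np.nan,
                "max_measure": est.bounds.max_measure if est.bounds else np.nan,
            }
        )
    return pd.DataFrame(rows)


def mcid(se: float, confidence: float = 0.95) -> float:
    """Minimum change exceeding measurement uncertainty at a confidence
    level: z(confidence) * se.

    With the conventional average person-measure error of 0.4 logit this
    gives 1.96 * 0.4 = 0.78 logit at 95% confidence - the smallest change
    in a person measure that can be scored as a real change rather than
    test-retest noise.
    """
    if not 0.0 < confidence < 1.0:
        raise DataValidationError("confidence must lie strictly in (0, 1)")
    if se < 0:
        raise DataValidationError("standard error must be non-negative")
    z = float(norm.ppf(0.5 + confidence / 2.0))
    return z * se
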