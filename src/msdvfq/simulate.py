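"""Synthetic rating-scale data with the structure the calibration assumes.

Responses are generated from the same cumulative-dichotomization model the
estimator fits,

    P(X_ni >= k) = sigma(theta_n - b_i - tau_k),
    P(X_ni = k)  = P(X >= k) - P(X >= k+1),

which is non-negative exactly because the thresholds are ordered.  Person
measures are drawn from a normal distribution.  The default configuration
mirrors the calibration cohort the packaged banks were built for: 3342
persons answering the 30-item 25C roster with five categories, person
measures ~ Normal(1.26, 1.99) logits, and the packaged item measures and
thresholds as generating values.

A misspecification mode (per-item threshold jitter, off by default)
breaks the shared-threshold assumption to probe robustness.

``simulate_vfq_raw`` additionally inverse-recodes the categories into the
questionnaire's native option numbering - including the driving gating
items, opt-out codes and driving-ineligible respondents - so the
instrument recoder can be exercised end to end without any external data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import RatingMatrix
from .exceptions import DataValidationError
from .instruments import InstrumentSpec, load_bank

__all__ = ["SimulationConfig", "simulate_responses", "simulate_vfq_raw"]


def _default_bank_values() -> tuple[np.ndarray, np.ndarray, list[str]]:
    bank = load_bank("25C")
    return (
        bank.items["measure"].to_numpy(dtype=float),
        bank.thresholds["estimate"].to_numpy(dtype=float),
        [str(i) for i in bank.items["item_id"]],
    )


@dataclass
class SimulationConfig:
    """Generating conditions for one synthetic dataset.

    Defaults emulate the calibration cohort: person measures
    Normal(1.26, 1.99) logits and the packaged 25C item measures and
    thresholds as generating values.  ``seed`` must be supplied
    explicitly; there is no implicit randomness.
    """

    seed: int
    n_persons: int = 3342
    item_measures: Optional[np.ndarray] = None
    thresholds: Optional[np.ndarray] = None
    item_ids: Optional[Sequence[str]] = None
    person_mean: float = 1.26
    person_sd: float = 1.99
    missing_rate: float = 0.0
    optout_rate: float = 0.0
    ineligible_driver_rate: float = 0.0
    threshold_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.item_measures is None or self.thresholds is None:
            b, tau, ids = _default_bank_values()
            if self.item_measures is None:
                self.item_measures = b
                if self.item_ids is None:
                    self.item_ids = ids
            if self.thresholds is None:
                self.thresholds = tau
        self.item_measures = np.asarray(self.item_measures, dtype=float)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim != 1 or len(self.thresholds) < 1:
            raise DataValidationError("thresholds must be a non-empty vector")
        if np.any(np.diff(self.thresholds) <= 0):
            raise DataValidationError("thresholds must be strictly increasing")
        for name in ("missing_rate", "optout_rate", "ineligible_driver_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise DataValidationError(f"{name} must lie in [0, 1)")
        if self.n_persons < 1:
            raise DataValidationError("n_persons must be positive")
        if self.person_sd <= 0:
            raise DataValidationError("person_sd must be positive")

    @property
    def m(self) -> int:
        return len(self.thresholds)


def simulate_responses(
    config: SimulationConfig, *, return_truth: bool = False
):
    """Draw a rating matrix from the cumulative model.

    With ``return_truth`` the generated person measures are returned as a
    second value, enabling parameter-recovery checks.
    """
    rng = np.random.default_rng(config.seed)
    n, b, tau = config.n_persons, config.item_measures, config.thresholds
    theta = rng.normal(config.person_mean, config.person_sd, size=n)
    if config.threshold_jitter_sd > 0:
        # Misspecification probe: each item gets privately jittered thresholds,
        # re-sorted to keep the category probabilities well defined.
        tau_items = tau[None, :] + rng.normal(
            0.0, config.threshold_jitter_sd, size=(len(b), len(tau))
        )
        tau_items.sort(axis=1)
        cum = expit(theta[:, None, None] - b[None, :, None] - tau_items[None, :, :])
    else:
        cum = expit(theta[:, None, None] - b[None, :, None] - tau[None, None, :])
    # A single uniform per cell against the decreasing survival curve
    # P(X>=k) samples the category pmf exactly.
    u = rng.uniform(size=(n, len(b)))
    X = (u[:, :, None] < cum).sum(axis=2).astype(float)
    if config.missing_rate > 0:
        X = np.where(rng.uniform(size=X.shape) < config.missing_rate, np.nan, X)
    matrix = RatingMatrix(
        X,
        config.m,
        [f"P{i + 1:04d}" for i in range(n)],
        list(config.item_ids) if config.item_ids is not None else None,
    )
    if return_truth:
        return matrix, theta
    return matrix


def _invert(table: dict) -> dict:
    return {cat: opt for opt, cat in table.items() if cat is not None}


def simulate_vfq_raw(
    config: SimulationConfig, spec: InstrumentSpec
) -> tuple[pd.DataFrame, RatingMatrix]:
    """Simulate native-format questionnaire records for an instrument.

    Returns the raw wide-format records and the underlying rating matrix
    they encode; ``recode_responses`` applied to the records reproduces
    that matrix entry for entry.  Respondents flagged driving-ineligible
    (never drove) have all driving items missing; respondents whose
    collapsed driving item lands in category 0 are represented as having
    stopped driving because of eyesight, which also places their other
    driving items in category 0.  Opt-out codes are injected at
    ``optout_rate`` into items whose native scale offers one.
    """
    cfg = SimulationConfig(
        seed=config.seed,
        n_persons=config.n_persons,
        item_measures=config.item_measures,
        thresholds=config.thresholds,
        item_ids=spec.item_ids,
        person_mean=config.person_mean,
        person_sd=config.person_sd,
        missing_rate=config.missing_rate,
        threshold_jitter_sd=config.threshold_jitter_sd,
    )
    matrix = simulate_responses(cfg)
    values = matrix.values.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 911]))
    n = matrix.n_persons
    item_pos = {iid: j for j, iid in enumerate(matrix.item_ids)}
    raw = pd.DataFrame(index=pd.Index(matrix.person_ids, name="person_id"))

    has_driving = any(it.driving for it in spec.items)
    ineligible = np.zeros(n, dtype=bool)
    if has_driving:
        ineligible = rng.uniform(size=n) < config.ineligible_driver_rate
        j30 = item_pos.get("30")
        cat30 = values[:, j30] if j30 is not None else np.full(n, np.nan)
        stopped = (~ineligible) & np.isfinite(cat30) & (cat30 == 0)
        if j30 is not None:
            values[ineligible, j30] = np.nan
        for iid in ("16", "16A"):
            if iid in item_pos:
                values[ineligible, item_pos[iid]] = np.nan
                values[stopped, item_pos[iid]] = 0.0
        q15 = np.where(ineligible | stopped, 2.0, 1.0)
        q15a = np.full(n, np.nan)
        q15a[ineligible] = 1.0
        q15a[stopped] = 2.0
        q15b = np.full(n, np.nan)
        q15b[stopped] = 1.0
        q15c = np.full(n, np.nan)
        drivers = ~(ineligible | stopped)
        with np.errstate(invalid="ignore"):
            q15c[drivers] = np.where(
                np.isfinite(cat30[drivers]), 5.0 - cat30[drivers], np.nan
            )
        raw["q15"] = q15
        raw["q15a"] = q15a
        raw["q15b"] = q15b
        raw["q15c"] = q15c

    for item in spec.items:
        if item.item_id == "30":
            continue
        j = item_pos[item.item_id]
        inverse = _invert(item.recode)
        col = np.full(n, np.nan)
        cats = values[:, j]
        for p in range(n):
            if item.driving and (ineligible[p] or (has_driving and raw["q15"].iloc[p] == 2.0)):
                # Non-drivers skip the item; the stopped-for-eyesight state
                # is encoded in the gating items, not here.
                continue
            if np.isfinite(cats[p]):
                col[p] = inverse[int(cats[p])]
        has_optout = item.recode is not None and any(
            v is None for v in item.recode.values()
        )
        if has_optout and config.optout_rate > 0:
            optout_code = next(k for k, v in item.recode.items() if v is None)
            hit = (rng.uniform(size=n) < config.optout_rate) & np.isfinite(col)
            col[hit] = optout_code
            values[hit, j] = np.nan
        raw[item.native] = col
    return raw, RatingMatrix(values, matrix.m, matrix.person_ids, matrix.item_ids)
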