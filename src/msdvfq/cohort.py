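"""Multi-dataset combination checks and targeting summaries.

Differential item functioning (DIF)
-----------------------------------
``dif_anova`` calibrates each dataset and the pooled dataset separately
and forms per-item deviations d_{i,g} = b_i^(g) - b_i^(pooled), each
calibration on its own mean-item-centered origin.  Two tests are
reported:

* ``anova`` - the one-way ANOVA of the deviations grouped by dataset.
  This is the classical reported analysis, but it is a test of group
  *means*, and mean-centering makes every group's mean deviation
  identically zero whenever all items are estimable in all groups; it is
  therefore conservative by construction (its p-value is near 1 for
  complete data) and is kept for comparability, not power.
* ``interaction`` - a split-half item-by-dataset interaction F test.
  Each dataset is split into two random half-samples and each half is
  calibrated separately; the half-sample item measures form a balanced
  two-way layout (items x datasets with two replicates per cell), and
  the dataset-by-item interaction mean square is compared against the
  within-cell (between-half) mean square.  Because a uniform shift of
  all items in one group is absorbed by that group's persons (scale
  indeterminacy), item-level *contrasts* are the only identifiable DIF
  signal; the interaction F targets exactly those, with a noise scale
  estimated from the data itself rather than from model standard errors
  (which understate sampling error for averaged dichotomization fits).

Targeting
---------
``targeting_summary`` reports the descriptive statistics used to judge
how well an instrument's items cover its persons: item-measure range and
spread, person-measure range and spread, the percentage of persons above
the hardest item, and the standard-error-versus-measure curves whose
crescent shape is characteristic of an unbounded logit scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RatingMatrix
from .exceptions import CalibrationError, DataValidationError
from .msd import MSDCalibration, msd_calibrate

__all__ = ["DifResult", "TargetingSummary", "dif_anova", "targeting_summary"]


@dataclass
class DifResult:
    """Item-measure deviations per dataset plus the DIF tests."""

    deviations: pd.DataFrame  # items x datasets
    anova_f: float
    anova_df_between: int
    anova_df_within: int
    anova_p: float
    interaction_f: float
    interaction_df1: int
    interaction_df2: int
    interaction_p: float
    quartiles: pd.DataFrame  # per dataset: q25, median, q75
    pooled: MSDCalibration
    calibrations: list[MSDCalibration]
    dataset_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "datasets": self.dataset_ids,
            "anova": {
                "F": self.anova_f,
                "df_between": self.anova_df_between,
                "df_within": self.anova_df_within,
                "p": self.anova_p,
            },
            "interaction": {
                "F": self.interaction_f,
                "df1": self.interaction_df1,
                "df2": self.interaction_df2,
                "p": self.interaction_p,
            },
            "quartiles": self.quartiles.to_dict(orient="index"),
        }


@dataclass
class TargetingSummary:
    """Descriptive targeting statistics for one calibration."""

    item_min: float
    item_max: float
    item_sd: float
    person_min: Optional[float] = None
    person_max: Optional[float] = None
    person_mean: Optional[float] = None
    person_sd: Optional[float] = None
    percent_above_hardest_item: Optional[float] = None
    item_curve: Optional[pd.DataFrame] = None  # measure vs se, sorted
    person_curve: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        out = {
            "item_min": self.item_min,
            "item_max": self.item_max,
            "item_sd": self.item_sd,
        }
        for key in (
            "person_min",
            "person_max",
            "person_mean",
            "person_sd",
            "percent_above_hardest_item",
        ):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        return out


def _split_half_item_measures(
    matrix: RatingMatrix, rng: np.random.Generator, **calibrate_kwargs
) -> Optional[np.ndarray]:
    """Item measures from two disjoint random half-samples (2 x items)."""
    perm = rng.permutation(matrix.n_persons)
    halves = []
    for idx in (perm[: matrix.n_persons // 2], perm[matrix.n_persons // 2 :]):
        sub = RatingMatrix(
            matrix.values[np.sort(idx)],
            matrix.m,
            [matrix.person_ids[i] for i in np.sort(idx)],
            list(matrix.item_ids),
        )
        try:
            halves.append(msd_calibrate(sub, **calibrate_kwargs).item_measures)
        except (CalibrationError, DataValidationError):
            return None
    return np.vstack(halves)


def _interaction_f(measures: np.ndarray) -> tuple[float, int, int, float]:
    """Balanced two-way ANOVA interaction test on half-sample measures.

    ``measures`` has shape (datasets, 2 halves, items), complete cases
    only.  Returns (F, df1, df2, p) for the dataset-by-item interaction
    tested against the within-cell (between-half) mean square.
    """
    G, r, I = measures.shape
    cell = measures.mean(axis=1)  # dataset x item means
    item_mean = cell.mean(axis=0)
    dataset_mean = cell.mean(axis=1)
    grand = cell.mean()
    resid = cell - item_mean[None, :] - dataset_mean[:, None] + grand
    ss_int = r * float((resid**2).sum())
    df_int = (G - 1) * (I - 1)
    ss_err = float(((measures - cell[:, None, :]) ** 2).sum())
    df_err = G * I * (r - 1)
    if df_int == 0 or df_err == 0 or ss_err == 0:
        return np.nan, df_int, df_err, np.nan
    f = (ss_int / df_int) / (ss_err / df_err)
    return f, df_int, df_err, float(stats.f.sf(f, df_int, df_err))


def dif_anova(
    datasets: Sequence[RatingMatrix],
    *,
    pooled: Optional[RatingMatrix] = None,
    dataset_ids: Optional[Sequence[str]] = None,
    split_seed: int = 0,
    **calibrate_kwargs,
) -> DifResult:
    """Test whether datasets sharing an item roster can be pooled.

    Each dataset and the pooled dataset are calibrated unanchored; items
    inestimable in a dataset contribute no deviation for that dataset.
    Datasets whose calibration fails entirely are excluded with a
    warning.  With fewer than two surviving datasets the test statistics
    are NaN (the deviations are still returned).  ``split_seed`` fixes
    the random half-sample split behind the interaction test.
    """
    if not datasets:
        raise DataValidationError("no datasets supplied")
    if dataset_ids is None:
        dataset_ids = [f"dataset_{g + 1}" for g in range(len(datasets))]
    dataset_ids = [str(d) for d in dataset_ids]
    if pooled is None:
        pooled = RatingMatrix.vstack(datasets)
    pooled_cal = msd_calibrate(pooled, **calibrate_kwargs)

    kept_ids: list[str] = []
    calibrations: list[MSDCalibration] = []
    for gid, matrix in zip(dataset_ids, datasets):
        if matrix.item_ids != pooled.item_ids:
            raise DataValidationError(
                f"dataset {gid!r} does not share the pooled item roster"
            )
        try:
            calibrations.append(msd_calibrate(matrix, **calibrate_kwargs))
        except CalibrationError:
            warnings.warn(f"dataset {gid!r}: calibration failed, excluded")
            continue
        kept_ids.append(gid)

    item_ids = pooled_cal.item_ids
    dev = pd.DataFrame(
        {
            gid: cal.item_measures - pooled_cal.item_measures
            for gid, cal in zip(kept_ids, calibrations)
        },
        index=item_ids,
    )
    quartiles = pd.DataFrame(
        {
            gid: {
                "q25": np.nanpercentile(dev[gid], 25),
                "median": np.nanpercentile(dev[gid], 50),
                "q75": np.nanpercentile(dev[gid], 75),
            }
            for gid in kept_ids
        }
    ).T

    anova_f = anova_p = np.nan
    df_between = df_within = 0
    int_f = int_p = np.nan
    int_df1 = int_df2 = 0
    if len(kept_ids) >= 2:
        groups = [dev[gid].dropna().to_numpy() for gid in kept_ids]
        groups = [g for g in groups if g.size > 0]
        if len(groups) >= 2:
            anova_f, anova_p = stats.f_oneway(*groups)
            df_between = len(groups) - 1
            df_within = sum(g.size for g in groups) - len(groups)

        rng = np.random.default_rng(split_seed)
        halves = []
        for gid, matrix in zip(dataset_ids, datasets):
            if gid not in kept_ids:
                continue
            half = _split_half_item_measures(matrix, rng, **calibrate_kwargs)
            if half is None:
                warnings.warn(
                    f"dataset {gid!r}: half-sample calibration failed; "
                    "interaction test skipped"
                )
                halves = []
                break
            halves.append(half)
        if len(halves) >= 2:
            stacked = np.stack(halves)  # datasets x 2 x items
            complete_items = np.all(np.isfinite(stacked), axis=(0, 1))
            if complete_items.sum() >= 2:
                int_f, int_df1, int_df2, int_p = _interaction_f(
                    stacked[:, :, complete_items]
                )

    return DifResult(
        deviations=dev,
        anova_f=float(anova_f),
        anova_df_between=df_between,
        anova_df_within=df_within,
        anova_p=float(anova_p),
        interaction_f=float(int_f),
        interaction_df1=int_df1,
        interaction_df2=int_df2,
        interaction_p=float(int_p),
        quartiles=quartiles,
        pooled=pooled_cal,
        calibrations=calibrations,
        dataset_ids=kept_ids,
    )


def targeting_summary(calibration: MSDCalibration) -> TargetingSummary:
    """Descriptive statistics of item and person measures.

    Spreads use the sample standard deviation (n-1 denominator); the
    percent of persons above the hardest item counts strictly greater
    measures.  Person-side fields are None for banks carrying no person
    measures.
    """
    b = np.asarray(calibration.item_measures, dtype=float)
    b = b[np.isfinite(b)]
    if b.size == 0:
        raise DataValidationError("calibration has no finite item measures")
    item_order = np.argsort(calibration.item_measures)
    summary = TargetingSummary(
        item_min=float(b.min()),
        item_max=float(b.max()),
        item_sd=float(b.std(ddof=1)) if b.size > 1 else np.nan,
        item_curve=pd.DataFrame(
            {
                "measure": np.asarray(calibration.item_measures)[item_order],
                "se": np.asarray(calibration.item_se)[item_order],
            }
        ),
    )
    theta = calibration.person_measures
    if theta is not None:
        theta = np.asarray(theta, dtype=float)
        finite = np.isfinite(theta)
        if finite.any():
            t = theta[finite]
            summary.person_min = float(t.min())
            summary.person_max = float(t.max())
            summary.person_mean = float(t.mean())
            summary.person_sd = float(t.std(ddof=1)) if t.size > 1 else np.nan
            summary.percent_above_hardest_item = float(
                100.0 * np.mean(t > summary.item_max)
            )
            order = np.argsort(t)
            se = np.asarray(calibration.person_se, dtype=float)[finite]
            summary.person_curve = pd.DataFrame(
                {"measure": t[order], "se": se[order]}
            )
    return summary
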