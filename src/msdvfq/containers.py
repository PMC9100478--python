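"""Shared containers for rating data and measurement results.

Missing responses are represented as NaN throughout; response matrices are
float arrays whose non-missing entries are integers.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataValidationError

__all__ = [
    "RatingMatrix",
    "PersonEstimate",
    "MeasureBounds",
    "ScoringStatus",
]


class ScoringStatus(str, Enum):
    """Outcome of a person-measure estimation attempt.

    ``estimated``: a finite maximum-likelihood measure exists.
    ``ceiling``/``floor``: every answered response was the top/bottom
    category, so the likelihood has no interior maximum and the measure is
    reported missing together with the instrument's estimable bounds.
    ``no_data``: no item was answered.
    """

    ESTIMATED = "estimated"
    CEILING = "ceiling"
    FLOOR = "floor"
    NO_DATA = "no_data"


@dataclass
class MeasureBounds:
    """Extreme person measures that remain estimable on an item subset.

    ``max_measure`` solves the score equation one raw-score unit below the
    maximum attainable raw score over the answered items; ``min_measure``
    solves it at raw score 1.  Any respondent with an all-top (all-bottom)
    response pattern has a true measure above ``max_measure`` (below
    ``min_measure``) even though no finite MLE exists.
    """

    min_measure: float
    max_measure: float
    item_subset: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.min_measure < self.max_measure:
            raise DataValidationError(
                f"min_measure ({self.min_measure}) must be below "
                f"max_measure ({self.max_measure})"
            )


@dataclass
class PersonEstimate:
    """A person measure with its precision and estimability status."""

    measure: float
    se: float
    raw_score: int
    n_answered: int
    status: ScoringStatus
    bounds: Optional[MeasureBounds] = None

    @property
    def estimated(self) -> bool:
        return self.status == ScoringStatus.ESTIMATED


@dataclass
class RatingMatrix:
    """Person x item integer ratings in categories 0..m, NaN for missing.

    All items share a single category range (the rating-scale convention:
    one set of thresholds for the whole instrument), so ``m`` is a property
    of the matrix, not of individual items.
    """

    values: np.ndarray
    m: int
    person_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]
    item_ids: Sequence[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DataValidationError("response matrix must be 2-dimensional")
        if values.size == 0:
            raise DataValidationError("response matrix is empty")
        if self.m < 1:
            raise DataValidationError("top category index m must be >= 1")
        obs = np.isfinite(values)
        observed = values[obs]
        if observed.size and not np.allclose(observed, np.round(observed)):
            bad = np.argwhere(obs & ~np.isclose(values, np.round(values)))[0]
            raise DataValidationError(
                f"non-integer response at row {bad[0]}, column {bad[1]}"
            )
        if observed.size and (observed.min() < 0 or observed.max() > self.m):
            bad = np.argwhere(obs & ((values < 0) | (values > self.m)))[0]
            raise DataValidationError(
                f"response out of range 0..{self.m} at row {bad[0]}, "
                f"column {bad[1]}"
            )
        self.values = values
        if self.person_ids is None:
            self.person_ids = [f"P{i + 1:04d}" for i in range(values.shape[0])]
        if self.item_ids is None:
            self.item_ids = [f"I{j + 1:02d}" for j in range(values.shape[1])]
        self.person_ids = list(map(str, self.person_ids))
        self.item_ids = list(map(str, self.item_ids))
        if len(self.person_ids) != values.shape[0]:
            raise DataValidationError("person_ids length mismatch")
        if len(self.item_ids) != values.shape[1]:
            raise DataValidationError("item_ids length mismatch")
        if len(set(self.person_ids)) != len(self.person_ids):
            raise DataValidationError("duplicate person ids")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise DataValidationError("duplicate item ids")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return np.isfinite(self.values)

    def subset_items(self, item_ids: Sequence[str]) -> "RatingMatrix":
        """Column subset in the order given, keeping all persons."""
        index = {iid: j for j, iid in enumerate(self.item_ids)}
        missing = [i for i in item_ids if i not in index]
        if missing:
            raise DataValidationError(f"unknown item ids: {missing}")
        cols = [index[i] for i in item_ids]
        return RatingMatrix(
            self.values[:, cols], self.m, self.person_ids, list(item_ids)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.person_ids), columns=list(self.item_ids)
        ).rename_axis("person_id")

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, m: int) -> "RatingMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            m,
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
        )

    @classmethod
    def vstack(
        cls, matrices: Sequence["RatingMatrix"], tag_persons: bool = True
    ) -> "RatingMatrix":
        """Pool datasets that share an item roster and category range.

        Person ids are prefixed with a dataset tag when ``tag_persons`` so
        the pooled matrix keeps unique ids.
        """
        if not matrices:
            raise DataValidationError("nothing to pool")
        first = matrices[0]
        for mat in matrices[1:]:
            if mat.item_ids != first.item_ids:
                raise DataValidationError("pooled datasets must share items")
            if mat.m != first.m:
                raise DataValidationError("pooled datasets must share m")
        values = np.vstack([mat.values for mat in matrices])
        if tag_persons:
            person_ids = [
                f"g{g}:{pid}"
                for g, mat in enumerate(matrices)
                for pid in mat.person_ids
            ]
        else:
            person_ids = [pid for mat in matrices for pid in mat.person_ids]
        return cls(values, first.m, person_ids, list(first.item_ids))
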