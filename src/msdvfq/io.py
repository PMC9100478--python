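"""CSV/JSON input and output.

All tabular interchange is RFC-4180 CSV with a header row, decimal point
and UTF-8; missing values are empty cells (a few common NA spellings are
also accepted on input).  Calibrations are written as two files: an item
block (item_id, measure, se) and a threshold block (threshold_index,
estimate, se).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .containers import RatingMatrix
from .exceptions import DataValidationError
from .msd import MSDCalibration

__all__ = [
    "read_rating_matrix",
    "write_rating_matrix",
    "read_calibration",
    "write_calibration",
    "sha256_file",
    "write_manifest",
]

_NA_STRINGS = ("", "NA", "na", "NaN", "nan", "N/A")

PathLike = Union[str, Path]


def read_rating_matrix(
    path: PathLike,
    *,
    m: Optional[int] = None,
    dialect: str = "wide",
) -> RatingMatrix:
    """Read a rating matrix from CSV.

    Wide dialect: first column holds person ids, remaining columns are
    item ids.  Long dialect: columns person_id, item_id, response.  The
    top category ``m`` is inferred from the data when not given; when
    given, any larger response is rejected with the offending cell named.
    """
    path = Path(path)
    if dialect == "wide":
        frame = pd.read_csv(
            path, index_col=0, na_values=list(_NA_STRINGS), keep_default_na=False
        )
    elif dialect == "long":
        long = pd.read_csv(path, na_values=list(_NA_STRINGS), keep_default_na=False)
        needed = {"person_id", "item_id", "response"}
        if not needed.issubset(long.columns):
            raise DataValidationError(
                "long format needs columns person_id, item_id, response"
            )
        frame = long.pivot_table(
            index="person_id", columns="item_id", values="response", aggfunc="first"
        )
    else:
        raise DataValidationError(f"unknown dialect {dialect!r}")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate person ids: {dupes}")
    values = np.full(frame.shape, np.nan)
    for j, col in enumerate(frame.columns):
        for i, cell in enumerate(frame[col]):
            if pd.isna(cell):
                continue
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise DataValidationError(
                    f"non-numeric cell at row {frame.index[i]!r}, "
                    f"column {col!r}: {cell!r}"
                ) from None
            if not v.is_integer():
                raise DataValidationError(
                    f"non-integer cell at row {frame.index[i]!r}, "
                    f"column {col!r}: {cell!r}"
                )
            values[i, j] = v
    observed = values[np.isfinite(values)]
    if observed.size == 0:
        raise DataValidationError(f"{path}: no observed responses")
    inferred = int(observed.max())
    if m is None:
        m = max(inferred, 1)
    else:
        if inferred > m:
            i, j = np.argwhere(np.isfinite(values) & (values > m))[0]
            raise DataValidationError(
                f"category {int(values[i, j])} exceeds top category {m} at "
                f"row {frame.index[i]!r}, column {frame.columns[j]!r}"
            )
    return RatingMatrix(
        values, m, [str(i) for i in frame.index], [str(c) for c in frame.columns]
    )


def write_rating_matrix(matrix: RatingMatrix, path: PathLike) -> None:
    frame = matrix.to_dataframe()
    out = frame.map(lambda v: "" if not np.isfinite(v) else str(int(v)))
    out.to_csv(path)


def read_calibration(
    items_path: PathLike, thresholds_path: PathLike
) -> MSDCalibration:
    items = pd.read_csv(items_path)
    thresholds = pd.read_csv(thresholds_path)
    for frame, cols, name in (
        (items, {"item_id", "measure", "se"}, "item"),
        (thresholds, {"threshold_index", "estimate", "se"}, "threshold"),
    ):
        if not cols.issubset(frame.columns):
            raise DataValidationError(f"{name} file must have columns {sorted(cols)}")
    return MSDCalibration(
        item_ids=[str(i) for i in items["item_id"]],
        item_measures=items["measure"].to_numpy(dtype=float),
        item_se=items["se"].to_numpy(dtype=float),
        thresholds=thresholds["estimate"].to_numpy(dtype=float),
        threshold_se=thresholds["se"].to_numpy(dtype=float),
        m=len(thresholds),
    )


def write_calibration(
    calibration: MSDCalibration,
    items_path: PathLike,
    thresholds_path: PathLike,
    persons_path: Optional[PathLike] = None,
) -> None:
    calibration.items_frame().to_csv(items_path, index=False)
    calibration.thresholds_frame().to_csv(thresholds_path, index=False)
    if persons_path is not None:
        calibration.persons_frame().to_csv(persons_path, index=False)


def sha256_file(path: PathLike) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path: PathLike,
    command: str,
    *,
    seed: Optional[int] = None,
    inputs: Sequence[PathLike] = (),
    outputs: Sequence[PathLike] = (),
    extra: Optional[dict] = None,
) -> None:
    """Write a JSON run manifest (tool version, seed, file checksums).

    Deliberately carries no timestamp so identical runs produce identical
    manifests.
    """
    manifest = {
        "tool": "msdvfq",
        "version": __version__,
        "command": command,
        "seed": seed,
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "outputs": {str(p): sha256_file(p) for p in outputs},
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
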