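"""NEI VFQ-25C / VF / SE instrument definitions and packaged item banks.

The 25C instrument drops the two general health/vision items from the
native questionnaire, keeps the remaining 24 items plus the six appendix
items, and collapses the four driving gating/rating questions (15, 15a,
15b, 15c) into a single converted item 30, giving 30 items rated on a
shared five-category scale (0 = least function, 4 = greatest function).
The VF instrument is its 20 visual-function items (three driving
related), the SE instrument its 10 socioemotional items; the two pain
items split between them (item 4 to VF, item 19 to SE).

Recoding rules
--------------
Raw responses use the questionnaire's native option numbering; per-type
recode tables (shipped as reviewable configuration under ``data/``)
orient every item so a higher category means greater function.  Any
"stopped doing this for other reasons / not interested" opt-out option
maps to missing.  Driving items are wholly missing for respondents who
never drove or who gave up driving for reasons other than eyesight alone
(gating item 15b response 2 or 3); respondents who stopped driving mainly
because of eyesight contribute the bottom category on all three driving
items, preserving the five-category range.

Item banks
----------
``load_bank`` returns the packaged calibrated item measures and shared
rating category thresholds for each instrument, checked against stored
SHA-256 digests so a corrupted installation fails closed.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .containers import RatingMatrix
from .exceptions import ChecksumError, DataValidationError
from .msd import MSDCalibration

__all__ = [
    "ItemDef",
    "InstrumentSpec",
    "ItemBank",
    "load_instrument",
    "load_bank",
    "recode_responses",
    "composite_score",
    "INSTRUMENT_IDS",
]

INSTRUMENT_IDS = ("25C", "VF", "SE")

_BANK_FILES = {
    "25C": ("items_25c.csv", "thresholds_25c.csv"),
    "VF": ("items_vf.csv", "thresholds_vf.csv"),
    "SE": ("items_se.csv", "thresholds_se.csv"),
}

#: Native wide-format columns recognised by the recoder.
NATIVE_COLUMNS = (
    ["q1", "q2"]
    + [f"q{i}" for i in range(3, 15)]
    + ["q15", "q15a", "q15b", "q15c", "q16", "q16a"]
    + [f"q{i}" for i in range(17, 26)]
    + [f"a{i}" for i in range(3, 9)]
)


def _data_dir() -> Path:
    return Path(resources.files("msdvfq") / "data")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _verified_read(name: str, data_dir: Optional[Path] = None) -> Path:
    """Resolve a packaged data file and verify its stored checksum."""
    base = Path(data_dir) if data_dir is not None else _data_dir()
    manifest_path = base / "banks.json"
    if not manifest_path.exists():
        raise ChecksumError(f"integrity manifest missing in {base}")
    manifest = json.loads(manifest_path.read_text())
    path = base / name
    if not path.exists():
        raise ChecksumError(f"packaged file {name} missing")
    expected = manifest.get("checksums", {}).get(name)
    if expected is None:
        raise ChecksumError(f"no checksum recorded for {name}")
    actual = _sha256(path)
    if actual != expected:
        raise ChecksumError(
            f"checksum mismatch for {name}: expected {expected}, got {actual}"
        )
    return path


@dataclass(frozen=True)
class ItemDef:
    """One converted instrument item and how to obtain it from raw data."""

    item_id: str
    native: str
    domain: str  # "VF" or "SE"
    driving: bool
    recode: Optional[Mapping[int, Optional[int]]]  # None for the collapsed item 30
    description: str


@dataclass(frozen=True)
class InstrumentSpec:
    """Ordered item roster and recoding rules for one instrument."""

    instrument_id: str
    items: tuple[ItemDef, ...]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def driving_items(self) -> list[str]:
        return [it.item_id for it in self.items if it.driving]

    @property
    def n_items(self) -> int:
        return len(self.items)


@dataclass
class ItemBank:
    """Packaged calibrated measures for one instrument."""

    instrument_id: str
    items: pd.DataFrame  # item_id, measure, se (+ metadata for 25C)
    thresholds: pd.DataFrame  # threshold_index, estimate, se

    def as_calibration(self) -> MSDCalibration:
        return MSDCalibration(
            item_ids=[str(i) for i in self.items["item_id"]],
            item_measures=self.items["measure"].to_numpy(dtype=float),
            item_se=self.items["se"].to_numpy(dtype=float),
            thresholds=self.thresholds["estimate"].to_numpy(dtype=float),
            threshold_se=self.thresholds["se"].to_numpy(dtype=float),
            m=len(self.thresholds),
        )


def _load_tables(data_dir: Optional[Path] = None) -> dict:
    base = Path(data_dir) if data_dir is not None else _data_dir()
    raw = json.loads((base / "recode_tables.json").read_text())
    tables = {}
    for name, table in raw["tables"].items():
        tables[name] = {
            int(k): (None if v is None else int(v))
            for k, v in table.items()
            if not k.startswith("_")
        }
    return {"tables": tables, "driving": raw["driving"]}


def load_instrument(instrument_id: str) -> InstrumentSpec:
    """Build the roster and recoding rules for ``25C``, ``VF`` or ``SE``."""
    iid = instrument_id.upper()
    if iid not in INSTRUMENT_IDS:
        raise DataValidationError(f"unknown instrument {instrument_id!r}")
    meta = pd.read_csv(_data_dir() / "items_25c.csv")
    cfg = _load_tables()
    items = []
    for row in meta.itertuples(index=False):
        if iid != "25C" and row.domain != iid:
            continue
        recode = None if row.recode == "driving" else cfg["tables"][row.recode]
        items.append(
            ItemDef(
                item_id=str(row.item_id),
                native=row.native,
                domain=row.domain,
                driving=bool(row.driving),
                recode=recode,
                description=row.description,
            )
        )
    return InstrumentSpec(instrument_id=iid, items=tuple(items))


def load_bank(
    instrument_id: str, data_dir: Optional[Union[str, Path]] = None
) -> ItemBank:
    """Load a packaged item bank at printed precision, verifying checksums.

    ``data_dir`` substitutes an alternative directory holding the same
    file layout (including its own ``banks.json`` manifest); it exists for
    testing and for locally re-calibrated banks.
    """
    iid = instrument_id.upper()
    if iid not in _BANK_FILES:
        raise DataValidationError(f"unknown instrument {instrument_id!r}")
    items_name, thresholds_name = _BANK_FILES[iid]
    data_dir = Path(data_dir) if data_dir is not None else None
    items = pd.read_csv(_verified_read(items_name, data_dir))
    thresholds = pd.read_csv(_verified_read(thresholds_name, data_dir))
    items["item_id"] = items["item_id"].astype(str)
    return ItemBank(instrument_id=iid, items=items, thresholds=thresholds)


def _as_option(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise DataValidationError(f"malformed option code {value!r}") from None
    if not float(f).is_integer():
        raise DataValidationError(f"malformed option code {value!r}")
    return int(f)


def _normalise_raw(
    raw: pd.DataFrame, dialect: str = "wide"
) -> pd.DataFrame:
    frame = raw.copy()
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    if dialect == "long":
        needed = {"person_id", "item_id", "option"}
        if not needed.issubset(frame.columns):
            raise DataValidationError(
                "long format needs columns person_id, item_id, option"
            )
        frame["item_id"] = frame["item_id"].astype(str).str.lower()
        frame = frame.pivot_table(
            index="person_id", columns="item_id", values="option", aggfunc="first"
        )
        frame.index = frame.index.astype(str)
    elif dialect == "wide":
        if "person_id" in frame.columns:
            frame = frame.set_index("person_id")
            frame.index = frame.index.astype(str)
        if frame.index.has_duplicates:
            raise DataValidationError("duplicate person ids in raw responses")
    else:
        raise DataValidationError(f"unknown dialect {dialect!r}")
    unknown = [c for c in frame.columns if c not in NATIVE_COLUMNS]
    if unknown:
        raise DataValidationError(f"unknown item ids in raw responses: {unknown}")
    return frame


def recode_responses(
    raw: pd.DataFrame, spec: InstrumentSpec, *, dialect: str = "wide"
) -> RatingMatrix:
    """Convert native NEI VFQ-25(+appendix) records into a rating matrix.

    ``raw`` is a wide table (columns = native item ids such as q3..q25,
    q15, q15a, q15b, q15c, q16, q16a, a3..a8; optional person_id column)
    or a long table (person_id, item_id, option).  Output columns follow
    the instrument's converted item ids; every retained item is recoded
    to categories 0..4 with higher category = greater function.
    """
    frame = _normalise_raw(raw, dialect)
    cfg = _load_tables()
    drv = cfg["driving"]
    driving4 = cfg["tables"]["driving4"]
    n = len(frame)
    out = np.full((n, spec.n_items), np.nan)

    def column(name: str) -> list[Optional[int]]:
        if name not in frame.columns:
            return [None] * n
        return [_as_option(v) for v in frame[name]]

    q15 = column("q15")
    q15a = column("q15a")
    q15b = column("q15b")
    q15c = column("q15c")

    # Per-person driving eligibility: "driver" rates the driving items,
    # "stopped_eyesight" contributes category 0, everything else is missing.
    driving_state = []
    for p in range(n):
        if q15[p] == drv["current_driver"]:
            driving_state.append("driver")
        elif q15[p] == drv["not_driving"]:
            if q15a[p] == drv["never_drove"]:
                driving_state.append("missing")
            elif q15a[p] == drv["gave_up"]:
                if q15b[p] == drv["stopped_eyesight"]:
                    driving_state.append("stopped_eyesight")
                elif q15b[p] in drv["stopped_other_codes"]:
                    driving_state.append("missing")
                else:
                    warnings.warn(
                        "gating item 15b missing or malformed; driving items "
                        "set to missing",
                        stacklevel=2,
                    )
                    driving_state.append("missing")
            else:
                driving_state.append("missing")
        else:
            if any(it.driving for it in spec.items):
                warnings.warn(
                    "gating item 15 missing; driving items set to missing",
                    stacklevel=2,
                )
            driving_state.append("missing")

    for j, item in enumerate(spec.items):
        if item.item_id == "30":
            for p in range(n):
                state = driving_state[p]
                if state == "driver":
                    opt = q15c[p]
                    if opt is None:
                        continue
                    if opt not in driving4:
                        raise DataValidationError(
                            f"invalid option {opt} for q15c (person "
                            f"{frame.index[p]!r})"
                        )
                    out[p, j] = driving4[opt]
                elif state == "stopped_eyesight":
                    out[p, j] = 0
            continue
        opts = column(item.native)
        for p in range(n):
            if item.driving:
                state = driving_state[p]
                if state == "missing":
                    continue
                if state == "stopped_eyesight":
                    out[p, j] = 0
                    continue
            opt = opts[p]
            if opt is None:
                continue
            if opt not in item.recode:
                raise DataValidationError(
                    f"invalid option {opt} for {item.native} (person "
                    f"{frame.index[p]!r})"
                )
            cat = item.recode[opt]
            out[p, j] = np.nan if cat is None else cat
    return RatingMatrix(out, 4, list(frame.index.astype(str)), spec.item_ids)


def composite_score(
    raw: pd.DataFrame,
    subscale_map: Optional[dict] = None,
    *,
    dialect: str = "wide",
) -> pd.DataFrame:
    """Legacy 0-100 composite score, retained only for comparison.

    Each rated item is recoded to 0-100 by the per-item value table in
    ``subscale_map`` (default: the packaged standard assignment), items
    are averaged within subscale, and the composite averages the subscale
    scores flagged ``in_composite`` (general health is excluded).
    Subscales with no rated item drop out of the composite average.
    """
    if subscale_map is None:
        subscale_map = json.loads((_data_dir() / "subscales.json").read_text())
    subscales = subscale_map.get("subscales", {})
    if not subscales:
        raise DataValidationError("empty subscale map")
    frame = _normalise_raw(raw, dialect)
    result = pd.DataFrame(index=frame.index)
    composite_cols = []
    for name, sub in subscales.items():
        values = np.full((len(frame), len(sub["items"])), np.nan)
        for j, (native, table) in enumerate(sub["items"].items()):
            if native not in frame.columns:
                continue
            lookup = {
                int(k): (np.nan if v is None else float(v))
                for k, v in table.items()
                if not str(k).startswith("_")
            }
            for p, v in enumerate(frame[native]):
                opt = _as_option(v)
                if opt is None:
                    continue
                if opt not in lookup:
                    raise DataValidationError(
                        f"invalid option {opt} for {native} (person "
                        f"{frame.index[p]!r})"
                    )
                values[p, j] = lookup[opt]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            result[name] = np.nanmean(values, axis=1)
        if sub.get("in_composite", True):
            composite_cols.append(name)
    if not composite_cols:
        raise DataValidationError("no subscales flagged for the composite")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        result["composite"] = np.nanmean(result[composite_cols].to_numpy(), axis=1)
    return result
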