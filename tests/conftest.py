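import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import msdvfq as mv

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py


@pytest.fixture(scope="session")
def bank_25c() -> mv.MSDCalibration:
    return mv.load_bank("25C").as_calibration()


@pytest.fixture(scope="session")
def bank_vf() -> mv.MSDCalibration:
    return mv.load_bank("VF").as_calibration()


@pytest.fixture(scope="session")
def bank_se() -> mv.MSDCalibration:
    return mv.load_bank("SE").as_calibration()


@pytest.fixture(scope="session")
def sim_500(bank_25c) -> tuple[mv.RatingMatrix, mv.SimulationConfig]:
    """One seeded 500-person dataset at the packaged generating values."""
    config = mv.SimulationConfig(seed=1, n_persons=500)
    return mv.simulate_responses(config), config


@pytest.fixture(scope="session")
def cal_500(sim_500) -> mv.MSDCalibration:
    matrix, _ = sim_500
    return mv.msd_calibrate(matrix)


def best_raw_record(person_id: str = "p1") -> dict:
    """Native record of an eligible driver answering every item at the
    greatest-function option (difficulty scales: 1; problem statements:
    5 = definitely false)."""
    record = {"person_id": person_id, "q3": 1, "q4": 1}
    for i in range(5, 15):
        record[f"q{i}"] = 1
    record.update({"q15": 1, "q15c": 1, "q16": 1, "q16a": 1})
    for i in range(17, 26):
        record[f"q{i}"] = 5
    for i in range(3, 9):
        record[f"a{i}"] = 1
    return record


def worst_raw_record(person_id: str = "p1") -> dict:
    """Native record at the least-function option everywhere; the
    respondent stopped driving because of eyesight (bottom category on
    all driving items)."""
    record = {"person_id": person_id, "q3": 5, "q4": 5}
    for i in range(5, 15):
        record[f"q{i}"] = 5
    record.update({"q15": 2, "q15a": 2, "q15b": 1})
    for i in range(17, 26):
        record[f"q{i}"] = 1
    for i in range(3, 9):
        record[f"a{i}"] = 5
    return record
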