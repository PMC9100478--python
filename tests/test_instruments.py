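"""Instrument rosters, native-option recoding, banks, composite score."""
import json
import shutil
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import msdvfq as mv
from msdvfq.exceptions import ChecksumError, DataValidationError

from conftest import best_raw_record, worst_raw_record


class TestRosters:
    def test_item_counts(self):
        assert mv.load_instrument("25C").n_items == 30
        assert mv.load_instrument("VF").n_items == 20
        assert mv.load_instrument("SE").n_items == 10

    def test_domains_partition_the_full_roster(self):
        full = set(mv.load_instrument("25C").item_ids)
        vf = set(mv.load_instrument("VF").item_ids)
        se = set(mv.load_instrument("SE").item_ids)
        assert vf | se == full
        assert not vf & se

    def test_three_driving_items_all_in_vf(self):
        vf = mv.load_instrument("VF")
        assert len(vf.driving_items) == 3
        assert set(vf.driving_items) == {"30", "16", "16A"}

    def test_pain_items_split_between_domains(self):
        assert "4" in mv.load_instrument("VF").item_ids
        assert "19" in mv.load_instrument("SE").item_ids

    def test_unknown_instrument_rejected(self):
        with pytest.raises(DataValidationError):
            mv.load_instrument("XX")


class TestRecode:
    def test_best_options_map_to_top_category(self):
        spec = mv.load_instrument("25C")
        matrix = mv.recode_responses(pd.DataFrame([best_raw_record()]), spec)
        np.testing.assert_array_equal(matrix.values[0], np.full(30, 4.0))

    def test_worst_options_map_to_bottom_category(self):
        spec = mv.load_instrument("25C")
        matrix = mv.recode_responses(pd.DataFrame([worst_raw_record()]), spec)
        np.testing.assert_array_equal(matrix.values[0], np.zeros(30))

    def test_never_drove_blanks_driving_items(self):
        record = best_raw_record()
        record.update({"q15": 2, "q15a": 1, "q15b": None, "q15c": None,
                       "q16": None, "q16a": None})
        spec = mv.load_instrument("25C")
        matrix = mv.recode_responses(pd.DataFrame([record]), spec)
        frame = matrix.to_dataframe()
        assert frame.loc["p1", ["30", "16", "16A"]].isna().all()
        assert frame.drop(columns=["30", "16", "16A"]).notna().all().all()

    def test_gave_up_for_other_reasons_blanks_driving_items(self):
        for code in (2, 3):
            record = best_raw_record()
            record.update({"q15": 2, "q15a": 2, "q15b": code, "q15c": None,
                           "q16": None, "q16a": None})
            matrix = mv.recode_responses(
                pd.DataFrame([record]), mv.load_instrument("25C")
            )
            assert matrix.to_dataframe().loc["p1", ["30", "16", "16A"]].isna().all()

    def test_opt_out_option_becomes_missing(self):
        record = best_raw_record()
        record["q5"] = 6
        matrix = mv.recode_responses(
            pd.DataFrame([record]), mv.load_instrument("25C")
        )
        assert np.isnan(matrix.to_dataframe().loc["p1", "5"])

    def test_domain_recode_is_column_subset_of_full(self):
        raw = pd.DataFrame([best_raw_record("p1"), worst_raw_record("p2")])
        full = mv.recode_responses(raw, mv.load_instrument("25C")).to_dataframe()
        for iid in ("VF", "SE"):
            sub = mv.recode_responses(raw, mv.load_instrument(iid)).to_dataframe()
            pd.testing.assert_frame_equal(sub, full[sub.columns])

    def test_unknown_column_rejected(self):
        raw = pd.DataFrame([{"person_id": "p", "q99": 1}])
        with pytest.raises(DataValidationError):
            mv.recode_responses(raw, mv.load_instrument("25C"))

    def test_malformed_option_rejected(self):
        record = best_raw_record()
        record["q5"] = 9
        with pytest.raises(DataValidationError):
            mv.recode_responses(pd.DataFrame([record]), mv.load_instrument("25C"))

    def test_long_format_round_trips_wide(self):
        record = best_raw_record()
        long = pd.DataFrame(
            [
                {"person_id": "p1", "item_id": k, "option": v}
                for k, v in record.items()
                if k != "person_id" and v is not None
            ]
        )
        spec = mv.load_instrument("25C")
        wide_matrix = mv.recode_responses(pd.DataFrame([record]), spec)
        long_matrix = mv.recode_responses(long, spec, dialect="long")
        np.testing.assert_array_equal(wide_matrix.values, long_matrix.values)


class TestBanks:
    def test_published_item_measures(self):
        items_25c = mv.load_bank("25C").items.set_index("item_id")
        assert items_25c.loc["16", "measure"] == 2.527
        assert items_25c.loc["16", "se"] == 0.028
        assert mv.load_bank("VF").items.set_index("item_id").loc["16", "measure"] == 3.069
        assert len(mv.load_bank("SE").items) == 10

    def test_thresholds_strictly_increasing(self):
        for iid in ("25C", "VF", "SE"):
            tau = mv.load_bank(iid).thresholds["estimate"].to_numpy()
            assert np.all(np.diff(tau) > 0)

    def test_corrupted_bank_fails_closed(self, tmp_path):
        src = Path(mv.instruments.__file__).parent / "data"
        dst = tmp_path / "data"
        shutil.copytree(src, dst)
        items = dst / "items_25c.csv"
        items.write_text(items.read_text().replace("2.527", "9.999"))
        with pytest.raises(ChecksumError):
            mv.load_bank("25C", data_dir=dst)
        # untouched files still verify
        assert mv.load_bank("SE", data_dir=dst).items.shape[0] == 10


class TestComposite:
    def test_ceiling_and_floor(self):
        best = dict(best_raw_record("p1"), q1=1, q2=1)
        scores = mv.composite_score(pd.DataFrame([best]))
        assert scores.loc["p1", "composite"] == pytest.approx(100.0)

        worst = dict(worst_raw_record("p2"), q1=5, q2=6)
        scores = mv.composite_score(pd.DataFrame([worst]))
        assert scores.loc["p2", "composite"] == pytest.approx(0.0)

    def test_toy_map_matches_hand_arithmetic(self):
        subscale_map = {
            "subscales": {
                "a": {
                    "in_composite": True,
                    "items": {
                        "q5": {"1": 100, "2": 50, "3": 0},
                        "q6": {"1": 100, "2": 50, "3": 0},
                    },
                },
                "b": {
                    "in_composite": True,
                    "items": {"q8": {"1": 100, "2": 0}},
                },
            }
        }
        raw = pd.DataFrame([{"person_id": "p", "q5": 1, "q6": 2, "q8": 2}])
        scores = mv.composite_score(raw, subscale_map)
        assert scores.loc["p", "a"] == pytest.approx(75.0)  # (100 + 50) / 2
        assert scores.loc["p", "b"] == pytest.approx(0.0)
        assert scores.loc["p", "composite"] == pytest.approx(37.5)

    def test_unrated_subscale_drops_out_of_composite(self):
        raw = pd.DataFrame([{"person_id": "p", "q12": 1}])
        scores = mv.composite_score(raw)
        assert scores.loc["p", "composite"] == pytest.approx(100.0)

    def test_empty_map_rejected(self):
        with pytest.raises(DataValidationError):
            mv.composite_score(pd.DataFrame([{"q5": 1}]), {"subscales": {}})
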