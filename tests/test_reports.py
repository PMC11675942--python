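"""Domain model, normalized IO, deduplication and the inclusion pipeline."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from glp1gi import FilterConfig, apply_filters, deduplicate
from glp1gi.reports import (
    OUTCOME_GRADE,
    REPORT_COLUMNS,
    Report,
    frame_to_reports,
    normalize_drug_name,
    read_normalized,
    reports_to_frame,
    write_normalized,
)
from conftest import make_reports


class TestReportModel:
    def test_validation_rejects_out_of_range(self):
        kw = dict(report_id="r", case_id="c", case_version=1, drug="exenatide",
                  role_code="primary_suspect", event_pt="nausea",
                  event_soc="gastrointestinal")
        with pytest.raises(ValueError):
            Report(**kw, age_years=150.0)
        with pytest.raises(ValueError):
            Report(**kw, reporting_year=1999)
        with pytest.raises(ValueError):
            Report(**dict(kw, drug="aspirin"))

    def test_outcome_grades(self):
        r = Report(report_id="r", case_id="c", case_version=1, drug="semaglutide",
                   role_code="primary_suspect", event_pt="nausea",
                   event_soc="gastrointestinal",
                   outcomes={"death", "hospitalization"})
        assert r.outcome_grades == {"death": 5, "hospitalization": 3}
        # severity grading covers every outcome flag
        assert set(OUTCOME_GRADE) == {"disability", "hospitalization",
                                      "life_threatening", "death"}

    @pytest.mark.parametrize(
        "raw,expected",
        [("BYETTA", "exenatide"), ("  Ozempic ", "semaglutide"),
         ("victoza", "liraglutide"), ("TRULICITY", "dulaglutide"),
         ("SOLIQUA", "lixisenatide"), ("metformin", "other"),
         ("semaglutide", "semaglutide")],
    )
    def test_drug_name_normalization(self, raw, expected):
        assert normalize_drug_name(raw) == expected


class TestNormalizedIO:
    def test_round_trip_identity(self, tmp_path):
        df = make_reports(
            [
                {"drug": "exenatide", "event_pt": "nausea",
                 "outcomes": "death|hospitalization"},
                {"drug": "semaglutide", "event_pt": "pancreatitis",
                 "age_years": np.nan, "sex": "unspecified"},
                {"drug": "liraglutide", "event_pt": "vomiting"},
            ]
        )
        path = tmp_path / "reports.csv"
        write_normalized(df, path)
        back = read_normalized(path)
        pd.testing.assert_frame_equal(df, back[REPORT_COLUMNS])
        assert back.attrs["ingest_warnings"] == {}
        # the dataclass view survives the same round trip
        assert frame_to_reports(df) == frame_to_reports(back)
        assert reports_to_frame(frame_to_reports(df)).equals(df)

    def test_dialect_value_mapping(self, tmp_path):
        df = make_reports([{"drug": "exenatide", "event_pt": "nausea"}])
        df.loc[0, "sex"] = "F"
        path = tmp_path / "d.csv"
        df.to_csv(path, index=False)
        back = read_normalized(path, field_maps={"sex": {"F": "female"}})
        assert back.loc[0, "sex"] == "female"
        assert back.attrs["ingest_warnings"] == {}

    def test_bad_age_becomes_missing_and_round_trips(self, tmp_path):
        df = make_reports([{"drug": "exenatide", "event_pt": "nausea"}])
        df["age_years"] = df["age_years"].astype(object)
        df.loc[0, "age_years"] = "-5"
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        once = read_normalized(path)
        assert np.isnan(once.loc[0, "age_years"])
        assert once.attrs["ingest_warnings"] == {"age_years": 1}
        path2 = tmp_path / "again.csv"
        write_normalized(once, path2)
        twice = read_normalized(path2)
        pd.testing.assert_frame_equal(once[REPORT_COLUMNS], twice[REPORT_COLUMNS])

    def test_missing_column_is_a_hard_error(self, tmp_path):
        path = tmp_path / "broken.csv"
        path.write_text("report_id,drug\nr1,exenatide\n")
        with pytest.raises(ValueError, match="event_pt"):
            read_normalized(path)

    def test_unknown_enum_maps_to_fallback_with_warning(self, tmp_path):
        df = make_reports([{"drug": "exenatide", "event_pt": "nausea"}])
        df.loc[0, "drug"] = "ASPIRIN???"
        path = tmp_path / "u.csv"
        df.to_csv(path, index=False)
        back = read_normalized(path)
        assert back.loc[0, "drug"] == "other"
        assert back.attrs["ingest_warnings"]["drug"] == 1


class TestDeduplicate:
    def test_max_version_wins(self):
        df = make_reports(
            [
                {"case_id": "C1", "case_version": 1, "drug": "exenatide",
                 "event_pt": "nausea"},
                {"case_id": "C1", "case_version": 2, "drug": "exenatide",
                 "event_pt": "nausea"},
                {"case_id": "C2", "case_version": 1, "drug": "liraglutide",
                 "event_pt": "vomiting"},
            ]
        )
        out = deduplicate(df)
        assert len(out) == 2
        assert out[out["case_id"] == "C1"]["case_version"].tolist() == [2]

    def test_exact_duplicates_collapse(self):
        one = make_reports([{"drug": "exenatide", "event_pt": "nausea"}])
        df = pd.concat([one] * 3, ignore_index=True)
        assert len(deduplicate(df)) == 1
        assert len(deduplicate(df, key="full_record")) == 1

    def test_idempotent_and_empty(self):
        df = make_reports([{"drug": "exenatide", "event_pt": "nausea"}])
        once = deduplicate(df)
        pd.testing.assert_frame_equal(once, deduplicate(once))
        assert deduplicate(df.iloc[0:0]).empty

    @given(st.permutations(list(range(6))))
    def test_order_invariance(self, perm):
        df = make_reports(
            [
                {"case_id": f"C{i % 3}", "case_version": 1 + i % 2,
                 "drug": "exenatide", "event_pt": f"pt{i}"}
                for i in range(6)
            ]
        )
        shuffled = df.iloc[list(perm)].reset_index(drop=True)
        pd.testing.assert_frame_equal(deduplicate(df), deduplicate(shuffled))


class TestApplyFilters:
    def test_stage_counts_on_constructed_set(self, ten_reports):
        kept, log = apply_filters(ten_reports)
        stages = {s: (i, e, o) for s, i, e, o in log.stages}
        assert stages["role_code"] == (10, 4, 6)
        assert len(kept) == 6

    def test_country_mismatch_retains_nothing(self, ten_reports):
        df = ten_reports.assign(country="CA")
        kept, log = apply_filters(df)
        assert kept.empty
        assert log.total_out == 0
        assert [s[0] for s in log.stages][-1] == "year_range"

    def test_log_conservation_and_chain(self, ten_reports):
        _, log = apply_filters(ten_reports)
        log.validate()
        total_excluded = sum(e for _, _, e, _ in log.stages)
        assert log.total_in - total_excluded == log.total_out

    def test_idempotence(self, ten_reports):
        once, _ = apply_filters(ten_reports)
        twice, log2 = apply_filters(once)
        pd.testing.assert_frame_equal(once, twice)
        assert all(e == 0 for _, _, e, _ in log2.stages)

    def test_monotone_in_constraints(self, ten_reports):
        base, _ = apply_filters(ten_reports, FilterConfig())
        tighter, _ = apply_filters(
            ten_reports, FilterConfig(year_range=(2021, 2023))
        )
        assert len(tighter) <= len(base)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(year_range=(2020, 2010))
        with pytest.raises(ValueError):
            apply_filters(
                make_reports([{"drug": "exenatide", "event_pt": "n"}]),
                FilterConfig(drop_missing=("no_such_field",)),
            )

    def test_excluding_all_drugs_yields_empty_with_full_log(self, ten_reports):
        kept, log = apply_filters(ten_reports, FilterConfig(drugs=frozenset()))
        assert kept.empty
        log.validate()

    def test_log_serialization(self, ten_reports):
        import json

        _, log = apply_filters(ten_reports)
        rows = json.loads(log.to_json())
        assert rows[0]["stage"] == "dedup"
        assert "role_code" in log.to_text()
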