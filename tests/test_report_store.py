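"""Ingestion, normalization, deduplication and filtering."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from faersig.report_store import (
    ReportSet,
    apply_demographic_filters,
    clean_drug_name,
    deduplicate,
    filter_event_reports,
    filter_primary_suspect,
    normalize_drug_names,
    parse_quarter_files,
    partition_event,
    read_flat,
    write_flat,
)
from conftest import mk_report


def _parse(paths):
    return parse_quarter_files(paths["DEMO"], paths["DRUG"], paths["REAC"], paths["OUTC"], paths["THER"])


class TestParsing:
    def test_empty_headered_files_give_empty_set(self, tmp_path):
        headers = {
            "DEMO": "primaryid$caseid$fda_dt$event_dt$age$sex$wt$occr_country",
            "DRUG": "primaryid$drug_seq$drugname$role_cod",
            "REAC": "primaryid$pt",
            "OUTC": "primaryid$outc_cod",
            "THER": "primaryid$dsg_drug_seq$start_dt$end_dt",
        }
        paths = {}
        for name, h in headers.items():
            p = tmp_path / f"{name}.txt"
            p.write_text(h + "\n")
            paths[name] = p
        rs = _parse(paths)
        assert rs.n_reports == 0
        assert rs.provenance["raw"] == 0

    def test_fixture_joins_and_counts_failures(self, quarter_files):
        rs = _parse(quarter_files)
        assert rs.provenance["raw"] == 12
        assert rs.n_reports == 9
        assert rs.audit["join_failures"] == 3
        assert set(rs.demo.index) == {f"R0{i}" for i in range(1, 10)}

    def test_implausible_age_survives_parsing(self, quarter_files):
        # parse/filter separation: the 121-year-old is filtered later
        rs = _parse(quarter_files)
        assert rs.demo.loc["R05", "age_years"] == 121

    def test_partial_dates_resolved(self, quarter_files):
        rs = _parse(quarter_files)
        assert rs.demo.loc["R03", "event_date"] == pd.Timestamp(2020, 3, 1)
        assert rs.demo.loc["R04", "event_date"] == pd.Timestamp(2019, 7, 1)

    def test_outcomes_and_therapy_dates_joined(self, quarter_files):
        rs = _parse(quarter_files)
        assert rs.demo.loc["R01", "outcomes"] == frozenset({"hospitalization"})
        assert rs.demo.loc["R02", "outcomes"] == frozenset({"death", "other-serious"})
        assert rs.demo.loc["R03", "outcomes"] == frozenset({"missing"})
        r01_drug = rs.drugs[rs.drugs["report_id"] == "R01"].iloc[0]
        assert r01_drug["therapy_start"] == pd.Timestamp(2020, 1, 1)

    def test_missing_file_is_fatal(self, quarter_files, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_quarter_files(
                tmp_path / "nope.txt", quarter_files["DRUG"], quarter_files["REAC"],
                quarter_files["OUTC"], quarter_files["THER"],
            )

    def test_malformed_line_skipped_and_counted(self, quarter_files):
        demo = quarter_files["DEMO"]
        demo.write_text(demo.read_text() + "bad$line$with$far$too$many$fields$x$y$z$q\n")
        rs = _parse(quarter_files)
        assert rs.audit["malformed_lines_demo"] == 1
        assert rs.n_reports == 9


class TestNormalization:
    def test_map_hit(self, quarter_files):
        rs = normalize_drug_names(_parse(quarter_files), {"LIPITOR": "ATORVASTATIN"})
        assert rs.drugs.loc[rs.drugs["report_id"] == "R01", "ingredient"].iloc[0] == "ATORVASTATIN"

    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("  atorvastatin calcium ", "ATORVASTATIN"),
            ("Metoprolol  Tartrate", "METOPROLOL"),
            ("SODIUM OXYBATE", "SODIUM OXYBATE"),  # salt prefix is not stripped
            ("plain", "PLAIN"),
        ],
    )
    def test_cleanup_rules(self, raw, expected):
        assert clean_drug_name(raw) == expected

    def test_idempotence(self, quarter_files):
        nm = {"LIPITOR": "ATORVASTATIN"}
        once = normalize_drug_names(_parse(quarter_files), nm)
        twice = normalize_drug_names(once, nm)
        pd.testing.assert_series_equal(once.drugs["ingredient"], twice.drugs["ingredient"])


class TestDeduplication:
    def test_all_distinct_cases_unchanged(self, ten_report_set):
        out = deduplicate(ten_report_set)
        assert out.n_reports == ten_report_set.n_reports

    def test_latest_version_survives(self):
        rs = ReportSet.from_reports([
            mk_report("V1", case="C1", version="2020-01-01"),
            mk_report("V2", case="C1", version="2021-06-01"),
            mk_report("V3", case="C2"),
        ])
        out = deduplicate(rs)
        assert set(out.demo.index) == {"V2", "V3"}

    def test_equal_dates_tie_broken_by_report_id(self):
        rs = ReportSet.from_reports([
            mk_report("100A", case="C1", version="2020-01-01"),
            mk_report("100B", case="C1", version="2020-01-01"),
        ])
        assert set(deduplicate(rs).demo.index) == {"100B"}

    def test_idempotence(self):
        rs = ReportSet.from_reports([
            mk_report("V1", case="C1", version="2020-01-01"),
            mk_report("V2", case="C1", version="2021-06-01"),
        ])
        once = deduplicate(rs)
        twice = deduplicate(once)
        pd.testing.assert_frame_equal(once.demo, twice.demo)


class TestEventFilter:
    def test_hand_count(self, ten_report_set):
        out = filter_event_reports(ten_report_set, {"CATARACT"})
        assert out.n_reports == 4

    def test_case_insensitive_match(self):
        rs = ReportSet.from_reports([mk_report("R1", reactions=("Cataract",))])
        assert filter_event_reports(rs, {"CATARACT"}).n_reports == 1

    def test_no_match_is_legal(self, ten_report_set):
        assert filter_event_reports(ten_report_set, {"CATARACT SUBCAPSULAR"}).n_reports == 0

    def test_empty_terms_fatal(self, ten_report_set):
        with pytest.raises(ValueError):
            filter_event_reports(ten_report_set, set())

    def test_partition(self, ten_report_set):
        cases, noncases = partition_event(ten_report_set, {"CATARACT"})
        assert cases.n_reports + noncases.n_reports == ten_report_set.n_reports
        assert set(cases.demo.index).isdisjoint(noncases.demo.index)
        assert set(cases.demo.index) | set(noncases.demo.index) == set(ten_report_set.demo.index)


class TestPrimarySuspectFilter:
    def test_sole_primary_suspect_retained(self):
        rs = ReportSet.from_reports([mk_report("R1", drug="X")])
        out = filter_primary_suspect(rs)
        assert out.n_reports == 1
        assert list(out.drugs["ingredient"]) == ["X"]

    def test_conflicting_roles_exclude_drug_and_report(self):
        from faersig.report_store import DrugEntry

        rs = ReportSet.from_reports([
            mk_report("R1", drug="X", extra_drugs=(DrugEntry("X", "X", "concomitant"),)),
        ])
        out = filter_primary_suspect(rs)
        assert out.n_reports == 0
        assert out.audit["reports_without_primary_suspect"] == 1

    def test_concomitant_other_drug_not_analysed(self):
        from faersig.report_store import DrugEntry

        rs = ReportSet.from_reports([
            mk_report("R1", drug="X", extra_drugs=(DrugEntry("Y", "Y", "concomitant"),)),
        ])
        out = filter_primary_suspect(rs)
        assert out.n_reports == 1
        assert list(out.drugs["ingredient"]) == ["X"]


class TestDemographicFilters:
    @pytest.mark.parametrize(
        "age, weight, sex, kept",
        [
            (120.0, 70.0, "female", True),
            (121.0, 70.0, "female", False),
            (65.0, 400.0, "male", True),
            (65.0, 400.1, "male", False),
            (65.0, 70.0, "unknown", False),
            (None, 70.0, "female", False),
            (65.0, None, "female", False),
        ],
    )
    def test_boundaries_and_completeness(self, age, weight, sex, kept):
        rs = ReportSet.from_reports([mk_report("R1", age=age, weight=weight, sex=sex)])
        assert apply_demographic_filters(rs).n_reports == (1 if kept else 0)


class TestCascadeProperties:
    def test_monotone_counts_and_ledger_consistency(self, quarter_files):
        rs = _parse(quarter_files)
        out = apply_demographic_filters(filter_primary_suspect(deduplicate(normalize_drug_names(rs))))
        stages = list(out.provenance.values())
        # raw >= ingested >= ... >= final
        assert all(a >= b for a, b in zip(stages, stages[1:]))
        assert stages[-1] == out.n_reports
        out.validate()

    def test_flat_round_trip(self, tmp_path, ten_report_set):
        path = tmp_path / "clean.tsv"
        write_flat(ten_report_set, path)
        back = read_flat(path)
        a = ten_report_set.demo.sort_index()
        b = back.demo.sort_index()
        for col in ("case_id", "version_date", "report_year", "age_years", "sex", "weight_kg", "country"):
            assert (a[col] == b[col]).all(), col
        assert all(set(x) == set(y) for x, y in zip(a["outcomes"], b["outcomes"]))
        assert set(map(tuple, ten_report_set.reactions.values)) == set(map(tuple, back.reactions.values))
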