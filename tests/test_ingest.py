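"""Dialect reading, partial dates, the deduplication rule, linking, cohorts."""

import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import srsignal as s
from srsignal.ingest import FormatError, load_bundle_dir, read_table


def _demo(rows):
    cols = ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "SEX", "AGE",
            "AGE_COD", "REPORTER_COUNTRY", "OCCP_COD"]
    return pd.DataFrame([dict(zip(cols, r + [""] * (len(cols) - len(r))))
                         for r in rows], columns=cols, dtype=str)


class TestReadTable:
    def test_header_only_file_gives_zero_records(self, tmp_path):
        p = tmp_path / "OUTC24Q3.txt"
        p.write_text("PRIMARYID$CASEID$OUTC_COD\n")
        assert len(read_table(p, "OUTC")) == 0

    def test_trailing_delimiter_tolerated(self, tmp_path):
        p = tmp_path / "OUTC24Q3.txt"
        p.write_text("PRIMARYID$CASEID$OUTC_COD\n45$1$HO$\n")
        frame = read_table(p, "OUTC")
        assert len(frame) == 1
        assert frame.iloc[0]["OUTC_COD"] == "HO"

    def test_missing_column_raises_naming_it(self, tmp_path):
        p = tmp_path / "OUTC24Q3.txt"
        p.write_text("PRIMARYID$CASEID\n45$1\n")
        with pytest.raises(FormatError, match="OUTC_COD"):
            read_table(p, "OUTC")

    def test_malformed_line_skipped_and_counted(self, tmp_path):
        p = tmp_path / "OUTC24Q3.txt"
        p.write_text("PRIMARYID$CASEID$OUTC_COD\n1$1$HO\n2$2$HO$XX$YY\n3$3$DE\n")
        log = {}
        frame = read_table(p, "OUTC", log=log)
        assert len(frame) == 2
        assert log["outc_lines_skipped"] == 1

    def test_round_trip_through_writer(self, planted_bundle, tmp_path):
        paths = s.write_faers_dialect(planted_bundle, tmp_path)
        log = {}
        tables = load_bundle_dir(tmp_path, log=log)
        for kind, original in planted_bundle.tables.items():
            pd.testing.assert_frame_equal(tables[kind], original)
        assert all(v == 0 for v in log.values())

    def test_empty_field_read_back_as_missing(self, tmp_path):
        p = tmp_path / "DEMO24Q3.txt"
        p.write_text("PRIMARYID$CASEID$FDA_DT$EVENT_DT$SEX$AGE$AGE_COD$"
                     "REPORTER_COUNTRY$OCCP_COD\n"
                     "11$1$20200101$$F$$YR$US$MD\n")
        row = read_table(p, "DEMO").iloc[0]
        assert row["EVENT_DT"] == "" and row["AGE"] == ""


@pytest.mark.parametrize("text,date,year,precision", [
    ("20200310", dt.date(2020, 3, 10), 2020, "day"),
    ("202003", dt.date(2020, 3, 1), 2020, "month"),
    ("2020", None, 2020, "year"),
    ("", None, None, "missing"),
    ("  ", None, None, "missing"),
    ("20201301", None, None, "missing"),  # month 13
    ("notadate", None, None, "missing"),
    ("20200310x", None, None, "missing"),
])
def test_parse_partial_date(text, date, year, precision):
    parsed = s.parse_partial_date(text)
    assert (parsed.date, parsed.year, parsed.precision) == (date, year, precision)


class TestDeduplicate:
    def test_most_recent_fda_dt_survives(self):
        demo = _demo([["10", "1", "20200101"], ["11", "1", "20200301"]])
        out = s.deduplicate(demo)
        assert list(out["PRIMARYID"]) == ["11"]

    def test_fda_dt_tie_broken_by_largest_primaryid(self):
        demo = _demo([["5", "2", "20200101"], ["9", "2", "20200101"]])
        out = s.deduplicate(demo)
        assert list(out["PRIMARYID"]) == ["9"]

    def test_all_unique_is_identity_sorted_by_caseid(self):
        demo = _demo([["9", "3", "20200101"], ["5", "1", "20200101"],
                      ["7", "2", "20200101"]])
        out = s.deduplicate(demo)
        assert list(out["CASEID"]) == ["1", "2", "3"]
        assert len(out) == 3

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(1, 99), st.integers(1, 9),
                  st.sampled_from(["20200101", "20200601", "20210101"])),
        min_size=1, max_size=30))
    def test_idempotent_and_one_row_per_caseid(self, triples):
        demo = _demo([[str(pid), str(cid), fda] for pid, cid, fda in triples])
        once = s.deduplicate(demo)
        assert once["CASEID"].is_unique
        twice = s.deduplicate(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_numeric_primaryid_comparison_not_lexicographic(self):
        demo = _demo([["9", "1", "20200101"], ["10", "1", "20200101"]])
        assert list(s.deduplicate(demo)["PRIMARYID"]) == ["10"]


class TestLinkReports:
    def _children(self, reac_rows, ther_rows=(), drug_rows=(), outc_rows=()):
        drug = pd.DataFrame(list(drug_rows) or [["11", "1", "1", "PS", "DRUG A"]],
                            columns=["PRIMARYID", "CASEID", "DRUG_SEQ",
                                     "ROLE_COD", "DRUGNAME"], dtype=str)
        reac = pd.DataFrame(list(reac_rows),
                            columns=["PRIMARYID", "CASEID", "PT"], dtype=str)
        ther = pd.DataFrame(list(ther_rows),
                            columns=["PRIMARYID", "CASEID", "DSG_DRUG_SEQ",
                                     "START_DT", "END_DT"], dtype=str)
        outc = pd.DataFrame(list(outc_rows),
                            columns=["PRIMARYID", "CASEID", "OUTC_COD"], dtype=str)
        return drug, reac, ther, outc

    def test_two_reactions_one_report(self):
        demo = _demo([["11", "1", "20200101", "20200110", "F", "50", "YR", "US", "MD"]])
        drug, reac, ther, outc = self._children(
            [["11", "1", "Myalgia"], ["11", "1", "Rash"]])
        reports = s.link_reports(demo, drug, reac, ther, outc)
        assert len(reports) == 1
        assert sorted(reports[0].reactions) == ["Myalgia", "Rash"]

    def test_report_without_reaction_excluded_and_counted(self):
        demo = _demo([["11", "1", "20200101"], ["21", "2", "20200101"]])
        drug, reac, ther, outc = self._children([["11", "1", "Myalgia"]])
        log = {}
        reports = s.link_reports(demo, drug, reac, ther, outc, log=log)
        assert len(reports) == 1
        assert log["reports_dropped_no_reaction"] == 1

    def test_earliest_parseable_therapy_start_for_target_drug(self):
        demo = _demo([["11", "1", "20200101", "20200310", "F", "", "", "US", "MD"]])
        drug, reac, ther, outc = self._children(
            [["11", "1", "Myalgia"]],
            ther_rows=[["11", "1", "1", "20200305", ""],
                       ["11", "1", "1", "20200101", ""]],
            drug_rows=[["11", "1", "1", "PS", "Drug A"]])
        reports = s.link_reports(demo, drug, reac, ther, outc,
                                 target_drug_names=["DRUG A"])
        assert reports[0].therapy_start == dt.date(2020, 1, 1)

    def test_age_normalized_to_years(self):
        demo = _demo([["11", "1", "20200101", "", "F", "600", "MON", "US", "MD"],
                      ["21", "2", "20200101", "", "M", "7", "DEC", "US", "MD"],
                      ["31", "3", "20200101", "", "M", "x", "YR", "US", "MD"]])
        drug, reac, ther, outc = self._children(
            [["11", "1", "Rash"], ["21", "2", "Rash"], ["31", "3", "Rash"]])
        reports = s.link_reports(demo, drug, reac, ther, outc)
        ages = {r.caseid: r.age_years for r in reports}
        assert ages["1"] == pytest.approx(50.0)
        assert ages["2"] == pytest.approx(70.0)
        assert ages["3"] is None


class TestPrimarySuspectCohort:
    def _report(self, caseid, drugs):
        return s.SafetyReport(primaryid=caseid, caseid=caseid,
                              fda_date=dt.date(2020, 1, 1), event_date=None,
                              event_year=None, sex="F", age_years=None,
                              country="US", reporter="MD", drugs=drugs,
                              reactions=["Rash"])

    def test_only_primary_suspect_role_included(self):
        reports = [self._report("1", [("FENOFIBRIC ACID", "PS")]),
                   self._report("2", [("FENOFIBRIC ACID", "SS")]),
                   self._report("3", [("FENOFIBRIC ACID", "C")])]
        cohort, background = s.primary_suspect_cohort(reports, ["FENOFIBRIC ACID"])
        assert [r.caseid for r in cohort] == ["1"]
        assert len(background) == 2

    def test_name_normalization(self):
        reports = [self._report("1", [("  Fenofibric   Acid ", "PS")])]
        cohort, _ = s.primary_suspect_cohort(reports, ["FENOFIBRIC ACID"])
        assert len(cohort) == 1

    def test_no_match_gives_empty_cohort_full_background(self):
        reports = [self._report("1", [("ASPIRIN", "PS")])]
        cohort, background = s.primary_suspect_cohort(reports, ["FENOFIBRIC ACID"])
        assert cohort == [] and len(background) == 1

    def test_partition_is_exhaustive(self, linked_cohort):
        cohort, background = linked_cohort
        assert len(cohort) > 0
        assert len({r.primaryid for r in cohort} & {r.primaryid for r in background}) == 0
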