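"""Reading, deduplicating and linking FAERS-dialect spontaneous-report tables.

The dialect: one "$"-delimited ASCII file per table with an uppercase header
row; empty fields between delimiters are missing values; dates are 8-digit
(YYYYMMDD), 6-digit (YYYYMM) or 4-digit (YYYY) strings.

Deduplication follows the FDA-recommended rule: reports are grouped by
CASEID; within a group the report with the most recent FDA_DT survives, and
ties on FDA_DT are broken by the largest PRIMARYID.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import normalize_name

REQUIRED_COLUMNS: dict[str, list[str]] = {
    "DEMO": ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "SEX", "AGE",
             "AGE_COD", "REPORTER_COUNTRY", "OCCP_COD"],
    "DRUG": ["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"],
    "REAC": ["PRIMARYID", "CASEID", "PT"],
    "THER": ["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"],
    "OUTC": ["PRIMARYID", "CASEID", "OUTC_COD"],
}

AGE_TO_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0, "WK": 1.0 / 52.0,
                "DY": 1.0 / 365.0, "HR": 1.0 / 8760.0}

PRIMARY_SUSPECT_ROLE = "PS"


class FormatError(ValueError):
    """Header does not match the expected table schema."""


@dataclass
class ParsedDate:
    """Partial-date parse result: a day-resolved date where the precision
    allows, plus the year whenever at least 4 digits were readable."""

    date: dt.date | None
    year: int | None
    precision: str  # "day" | "month" | "year" | "missing"


@dataclass
class SafetyReport:
    """One deduplicated case with its linked drug, reaction, therapy and
    outcome rows."""

    primaryid: str
    caseid: str
    fda_date: dt.date
    event_date: dt.date | None
    event_year: int | None
    sex: str  # "F" | "M" | "unknown"
    age_years: float | None
    country: str
    reporter: str
    drugs: list[tuple[str, str]] = field(default_factory=list)  # (name, role code)
    reactions: list[str] = field(default_factory=list)
    therapy_start: dt.date | None = None
    outcomes: list[str] = field(default_factory=list)

    @property
    def serious(self) -> bool:
        # Seriousness is defined at the case level: any reported outcome.
        return len(self.outcomes) > 0


def read_table(path: str | Path, table_kind: str, log: dict | None = None) -> pd.DataFrame:
    """Read one dialect file into a string DataFrame (missing -> "").

    A trailing delimiter (an empty final field not named in the header) is
    tolerated; lines with a genuinely wrong field count are skipped and
    counted in ``log``.
    """
    kind = table_kind.upper()
    if kind not in REQUIRED_COLUMNS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    path = Path(path)

    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path.name}: empty file")
    header = [h.strip().upper() for h in lines[0].split("$")]
    if header and header[-1] == "":
        header = header[:-1]
    missing = [c for c in REQUIRED_COLUMNS[kind] if c not in header]
    if missing:
        raise FormatError(f"{path.name}: {kind} header is missing column(s) {missing}")

    width = len(header)
    records: list[list[str]] = []
    skipped = 0
    for line in lines[1:]:
        fields = line.split("$")
        if len(fields) > width and all(x == "" for x in fields[width:]):
            fields = fields[:width]  # trailing delimiter(s): empty final field
        if len(fields) != width:
            skipped += 1
            continue
        records.append(fields)
    frame = pd.DataFrame(records, columns=header, dtype=str)
    if frame.empty:
        frame = pd.DataFrame({c: pd.Series(dtype=str) for c in header})
    if log is not None:
        log[f"{kind.lower()}_lines_skipped"] = skipped
    return frame


def parse_partial_date(text: str) -> ParsedDate:
    """8 digits -> exact day; 6 -> first of month; 4 -> year only (no date,
    unusable for onset intervals but usable for annual tables); anything else
    -> missing."""
    text = (text or "").strip()
    if not text.isdigit():
        return ParsedDate(None, None, "missing")
    try:
        if len(text) == 8:
            return ParsedDate(dt.date(int(text[:4]), int(text[4:6]), int(text[6:8])),
                              int(text[:4]), "day")
        if len(text) == 6:
            return ParsedDate(dt.date(int(text[:4]), int(text[4:6]), 1), int(text[:4]), "month")
        if len(text) == 4:
            return ParsedDate(None, int(text), "year")
    except ValueError:
        pass
    return ParsedDate(None, None, "missing")


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """One row per CASEID: keep the most recent FDA_DT, ties broken by the
    largest PRIMARYID. Output sorted by CASEID; idempotent."""
    work = demo.copy()
    work["_pid"] = pd.to_numeric(work["PRIMARYID"], errors="coerce")
    work = work.sort_values(["CASEID", "FDA_DT", "_pid"], kind="mergesort")
    survivors = work.groupby("CASEID", sort=True).tail(1)
    return survivors.drop(columns="_pid").sort_values("CASEID", kind="mergesort").reset_index(drop=True)


def _age_years(age: str, code: str) -> float | None:
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    factor = AGE_TO_YEARS.get((code or "").strip().upper())
    return value * factor if factor is not None else None


def link_reports(
    demo: pd.DataFrame,
    drug: pd.DataFrame,
    reac: pd.DataFrame,
    ther: pd.DataFrame,
    outc: pd.DataFrame,
    target_drug_names: list[str] | None = None,
    log: dict | None = None,
) -> list[SafetyReport]:
    """Join the child tables onto deduplicated DEMO rows by PRIMARYID.

    Reports with no reaction row are dropped (and counted in ``log``);
    ``therapy_start`` is the earliest parseable start date among therapy rows
    belonging to a drug row whose name matches ``target_drug_names``.
    """
    targets = {normalize_name(n) for n in (target_drug_names or [])}

    drug_by_pid: dict[str, list[tuple[str, str, str]]] = {}
    for row in drug.itertuples(index=False):
        drug_by_pid.setdefault(row.PRIMARYID, []).append(
            (row.DRUGNAME, row.ROLE_COD, row.DRUG_SEQ))
    reac_by_pid: dict[str, list[str]] = {}
    for row in reac.itertuples(index=False):
        reac_by_pid.setdefault(row.PRIMARYID, []).append(row.PT)
    ther_by_pid: dict[str, list[tuple[str, str]]] = {}
    for row in ther.itertuples(index=False):
        ther_by_pid.setdefault(row.PRIMARYID, []).append((row.DSG_DRUG_SEQ, row.START_DT))
    outc_by_pid: dict[str, list[str]] = {}
    for row in outc.itertuples(index=False):
        outc_by_pid.setdefault(row.PRIMARYID, []).append(row.OUTC_COD)

    reports: list[SafetyReport] = []
    dropped_no_reaction = 0
    dropped_bad_fda_date = 0
    for row in demo.itertuples(index=False):
        pid = row.PRIMARYID
        reactions = reac_by_pid.get(pid, [])
        if not reactions:
            dropped_no_reaction += 1
            continue
        fda = parse_partial_date(row.FDA_DT)
        if fda.date is None:
            dropped_bad_fda_date += 1
            continue
        event = parse_partial_date(row.EVENT_DT)
        drugs = [(name, role) for name, role, _seq in drug_by_pid.get(pid, [])]

        therapy_start: dt.date | None = None
        if targets:
            target_seqs = {seq for name, _role, seq in drug_by_pid.get(pid, [])
                           if normalize_name(name) in targets}
            for seq, start in ther_by_pid.get(pid, []):
                if seq in target_seqs:
                    parsed = parse_partial_date(start)
                    if parsed.date is not None and (therapy_start is None
                                                    or parsed.date < therapy_start):
                        therapy_start = parsed.date

        sex = (row.SEX or "").strip().upper()
        reports.append(SafetyReport(
            primaryid=pid,
            caseid=row.CASEID,
            fda_date=fda.date,
            event_date=event.date,
            event_year=event.year,
            sex=sex if sex in ("F", "M") else "unknown",
            age_years=_age_years(row.AGE, row.AGE_COD),
            country=(row.REPORTER_COUNTRY or "").strip().upper(),
            reporter=(row.OCCP_COD or "").strip().upper(),
            drugs=drugs,
            reactions=reactions,
            therapy_start=therapy_start,
            outcomes=outc_by_pid.get(pid, []),
        ))
    if log is not None:
        log["reports_dropped_no_reaction"] = dropped_no_reaction
        log["reports_dropped_bad_fda_date"] = dropped_bad_fda_date
        log["reports_linked"] = len(reports)
    return reports


def primary_suspect_cohort(
    reports: list[SafetyReport],
    drug_names: list[str],
    role_code: str = PRIMARY_SUSPECT_ROLE,
) -> tuple[list[SafetyReport], list[SafetyReport]]:
    """Split reports into (cohort, background): a report is in the cohort iff
    some drug row matches a target name (after trim/collapse/uppercase) in the
    primary-suspect role."""
    if not drug_names:
        raise ValueError("drug_names must be nonempty")
    targets = {normalize_name(n) for n in drug_names}
    cohort, background = [], []
    for report in reports:
        hit = any(normalize_name(name) in targets and role == role_code
                  for name, role in report.drugs)
        (cohort if hit else background).append(report)
    return cohort, background


def load_bundle_dir(directory: str | Path, log: dict | None = None) -> dict[str, pd.DataFrame]:
    """Read every dialect table found in a directory (DEMO*.txt etc.)."""
    directory = Path(directory)
    tables = {}
    for kind in REQUIRED_COLUMNS:
        matches = sorted(directory.glob(f"{kind}*.txt"))
        if not matches:
            raise FileNotFoundError(f"no {kind} table found in {directory}")
        frames = [read_table(p, kind, log=log) for p in matches]
        tables[kind] = pd.concat(frames, ignore_index=True)
    return tables
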