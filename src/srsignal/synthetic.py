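"""Synthetic spontaneous-report generator with known ground truth.

Emulates the quarterly ASCII tables of a FAERS-style spontaneous reporting
system (DEMO / DRUG / REAC / THER / OUTC, "$"-delimited) plus a
VigiAccess-style aggregate count table, so that every downstream stage —
deduplication, cohort extraction, disproportionality, time-to-onset — can be
tested against planted truth without any database download.

The generative model is deliberately simple: one primary-suspect drug per
report (the target drug with probability ``target_drug_rate``, otherwise a
background drug), and each preferred term (PT) assigned independently per
report with probability ``background_event_rate``, multiplied by the planted
relative risk when the report carries the target drug. Onset times are
Weibull-distributed days added to a uniformly drawn therapy start date.
Duplicate case reports are injected as a later re-report of an existing
CASEID with a larger PRIMARYID, so the deduplication survivor is known.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import quarter_label, yyyymmdd

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "THER", "OUTC")

# Background PT vocabulary (matches the bundled dictionary stub). The first
# entries are events the target drug is known or suspected to provoke in the
# field this emulates; the remainder are generic fillers.
BACKGROUND_PTS = [
    "Myalgia", "Blood creatine phosphokinase increased", "Blood creatinine increased",
    "Blood creatine increased", "Muscle fatigue", "Pain in extremity", "Arthralgia",
    "Headache", "Gout", "Hypoglycaemia", "Prothrombin time prolonged",
    "Photosensitivity reaction", "Rash", "Rhabdomyolysis", "Renal impairment",
    "Renal failure", "Hepatitis", "Hepatic enzyme increased", "Cholelithiasis",
    "Pancreatitis", "Dyspepsia", "Nausea", "Vomiting", "Diarrhoea", "Abdominal pain",
    "Constipation", "Fatigue", "Asthenia", "Dizziness", "Pruritus", "Urticaria",
    "Anaemia", "Muscle spasms", "Eye opacity", "Vision blurred", "Chest pain",
    "Dyspnoea", "Cough", "Insomnia", "Anxiety", "Depression", "Hypertension",
    "Palpitations", "Oedema peripheral", "Weight decreased", "Weight increased",
    "Decreased appetite", "Pyrexia", "Malaise", "Back pain", "Hyperhidrosis",
    "Alopecia", "Dry mouth", "Somnolence", "Tremor", "Paraesthesia", "Tinnitus",
    "Vertigo", "Epistaxis", "Flushing",
]

BACKGROUND_DRUG_STEMS = [
    "ATORVASTATIN", "SIMVASTATIN", "ROSUVASTATIN", "METFORMIN", "LISINOPRIL",
    "AMLODIPINE", "OMEPRAZOLE", "ASPIRIN", "WARFARIN", "LEVOTHYROXINE",
    "METOPROLOL", "LOSARTAN", "GABAPENTIN", "SERTRALINE", "ALBUTEROL",
    "FUROSEMIDE", "INSULIN GLARGINE", "CLOPIDOGREL", "PREDNISONE", "TRAMADOL",
]

COUNTRIES = ["US", "CA", "JP", "CN", "KR", "IN", "GB", "FR", "DE", "BR", "AU", "IT"]
COUNTRY_PROBS = [0.55, 0.05, 0.08, 0.08, 0.04, 0.04, 0.04, 0.03, 0.03, 0.03, 0.02, 0.01]
OCCUPATIONS = ["MD", "CN", "PH", "OT"]
OCCUPATION_PROBS = [0.52, 0.31, 0.10, 0.07]
OUTCOME_CODES = ["HO", "OT", "LT", "DS", "DE"]
OUTCOME_PROBS = [0.5, 0.3, 0.1, 0.05, 0.05]


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults emulate the study conditions of a
    single-drug post-marketing safety profile (83 quarters of reports, ~2 PTs
    per report, early-failure onset profile, heavy age missingness)."""

    n_reports: int = 5000
    n_background_drugs: int = 20
    n_background_events: int = 50
    target_drug: str = "FENOFIBRIC ACID"
    planted_signals: list[tuple[str, float]] = field(default_factory=list)
    target_drug_rate: float = 0.05
    background_event_rate: float = 0.04
    duplicate_rate: float = 0.05
    missing_age_rate: float = 0.70
    missing_sex_rate: float = 0.23
    missing_ther_date_rate: float = 0.30
    partial_event_date_rate: float = 0.0
    serious_rate: float = 0.17
    onset_shape: float = 0.68
    onset_scale: float = 45.0
    sex_split: float = 0.5
    date_range: tuple[dt.date, dt.date] = (dt.date(2004, 1, 1), dt.date(2024, 9, 30))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        if self.onset_shape <= 0 or self.onset_scale <= 0:
            raise ValueError("Weibull onset parameters must be positive")
        for name in ("duplicate_rate", "missing_age_rate", "missing_sex_rate",
                     "missing_ther_date_rate", "partial_event_date_rate",
                     "serious_rate", "sex_split", "target_drug_rate",
                     "background_event_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for ev, rr in self.planted_signals:
            if rr < 0:
                raise ValueError(f"relative risk for {ev!r} must be >= 0")
        if self.date_range[0] >= self.date_range[1]:
            raise ValueError("date_range start must precede end")


@dataclass
class SyntheticBundle:
    """Generated tables plus the ground-truth manifest."""

    tables: dict[str, pd.DataFrame]
    manifest: dict


def event_vocabulary(config: SyntheticConfig) -> list[str]:
    """Planted PTs first, padded with stock background PTs up to
    ``n_background_events`` names (generated fillers beyond the stock list)."""
    vocab = [ev for ev, _ in config.planted_signals]
    for pt in BACKGROUND_PTS:
        if len(vocab) >= config.n_background_events:
            break
        if pt not in vocab:
            vocab.append(pt)
    i = 1
    while len(vocab) < config.n_background_events:
        vocab.append(f"Background event {i:03d}")
        i += 1
    return vocab


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Draw a full report bundle. Deterministic for a fixed config (seed included)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    q = config.background_event_rate
    for ev, rr in config.planted_signals:
        if q * rr > 1.0:
            raise ValueError(
                f"planted relative risk {rr} for {ev!r} makes event probability "
                f"{q * rr:.3f} exceed 1; lower background_event_rate or the RR"
            )

    vocab = event_vocabulary(config)
    planted_idx = {vocab.index(ev): rr for ev, rr in config.planted_signals}

    caseid = 10_000_000 + np.arange(n)
    primaryid = caseid * 10 + 1

    start_epoch = config.date_range[0].toordinal()
    span = config.date_range[1].toordinal() - start_epoch
    ther_start_ord = start_epoch + rng.integers(0, span + 1, size=n)
    onset_days = np.rint(config.onset_scale * rng.weibull(config.onset_shape, size=n)).astype(int)
    event_ord = ther_start_ord + onset_days
    fda_ord = event_ord + rng.integers(0, 91, size=n)

    sex = np.where(rng.random(n) < config.sex_split, "F", "M")
    sex[rng.random(n) < config.missing_sex_rate] = ""
    age = rng.integers(18, 91, size=n).astype(object)
    age_missing = rng.random(n) < config.missing_age_rate
    country = rng.choice(COUNTRIES, size=n, p=COUNTRY_PROBS)
    occp = rng.choice(OCCUPATIONS, size=n, p=OCCUPATION_PROBS)
    serious = rng.random(n) < config.serious_rate
    has_target = rng.random(n) < config.target_drug_rate

    # Independent Bernoulli event assignment; planted PTs get q*RR given the drug.
    probs = np.full((n, len(vocab)), q)
    for j, rr in planted_idx.items():
        probs[has_target, j] = q * rr
    occurs = rng.random((n, len(vocab))) < probs

    # Primary-suspect drug per report; a few reports carry the target drug in a
    # non-suspect role so the role-code filter is exercised.
    bg_drugs = [f"{BACKGROUND_DRUG_STEMS[i % len(BACKGROUND_DRUG_STEMS)]}"
                if i < len(BACKGROUND_DRUG_STEMS) else f"BACKGROUND DRUG {i + 1}"
                for i in range(config.n_background_drugs)]
    ps_drug = np.array(bg_drugs, dtype=object)[rng.integers(0, len(bg_drugs), size=n)]
    ps_drug[has_target] = config.target_drug
    target_concomitant = (~has_target) & (rng.random(n) < 0.02)
    concomitant = rng.random(n) < 0.3

    def _dates(ords: np.ndarray) -> np.ndarray:
        return np.array([yyyymmdd(dt.date.fromordinal(int(o))) for o in ords], dtype=object)

    event_dt = _dates(event_ord)
    if config.partial_event_date_rate > 0:
        partial = rng.random(n) < config.partial_event_date_rate
        to_month = partial & (rng.random(n) < 0.5)
        to_year = partial & ~to_month
        event_dt[to_month] = [s[:6] for s in event_dt[to_month]]
        event_dt[to_year] = [s[:4] for s in event_dt[to_year]]

    demo = pd.DataFrame({
        "PRIMARYID": primaryid.astype(str),
        "CASEID": caseid.astype(str),
        "FDA_DT": _dates(fda_ord),
        "EVENT_DT": event_dt,
        "SEX": sex,
        "AGE": np.where(age_missing, "", age.astype(str)),
        "AGE_COD": np.where(age_missing, "", "YR"),
        "REPORTER_COUNTRY": country,
        "OCCP_COD": occp,
    })

    drug_rows = {"PRIMARYID": [], "CASEID": [], "DRUG_SEQ": [], "ROLE_COD": [], "DRUGNAME": []}
    ther_rows = {"PRIMARYID": [], "CASEID": [], "DSG_DRUG_SEQ": [], "START_DT": [], "END_DT": []}
    start_missing = rng.random(n) < config.missing_ther_date_rate
    start_dt = _dates(ther_start_ord)
    conc_pick = rng.integers(0, len(bg_drugs), size=n)
    for i in range(n):
        pid, cid = str(primaryid[i]), str(caseid[i])
        drug_rows["PRIMARYID"].append(pid)
        drug_rows["CASEID"].append(cid)
        drug_rows["DRUG_SEQ"].append("1")
        drug_rows["ROLE_COD"].append("PS")
        drug_rows["DRUGNAME"].append(ps_drug[i])
        seq = 2
        if target_concomitant[i]:
            drug_rows["PRIMARYID"].append(pid)
            drug_rows["CASEID"].append(cid)
            drug_rows["DRUG_SEQ"].append(str(seq))
            drug_rows["ROLE_COD"].append("C")
            drug_rows["DRUGNAME"].append(config.target_drug)
            seq += 1
        elif concomitant[i]:
            drug_rows["PRIMARYID"].append(pid)
            drug_rows["CASEID"].append(cid)
            drug_rows["DRUG_SEQ"].append(str(seq))
            drug_rows["ROLE_COD"].append("C")
            drug_rows["DRUGNAME"].append(bg_drugs[conc_pick[i]])
            seq += 1
        ther_rows["PRIMARYID"].append(pid)
        ther_rows["CASEID"].append(cid)
        ther_rows["DSG_DRUG_SEQ"].append("1")
        ther_rows["START_DT"].append("" if start_missing[i] else start_dt[i])
        ther_rows["END_DT"].append("")
    drug = pd.DataFrame(drug_rows)
    ther = pd.DataFrame(ther_rows)

    rep_idx, ev_idx = np.nonzero(occurs)
    reac = pd.DataFrame({
        "PRIMARYID": primaryid[rep_idx].astype(str),
        "CASEID": caseid[rep_idx].astype(str),
        "PT": [vocab[j] for j in ev_idx],
    })

    ser_idx = np.nonzero(serious)[0]
    outc = pd.DataFrame({
        "PRIMARYID": primaryid[ser_idx].astype(str),
        "CASEID": caseid[ser_idx].astype(str),
        "OUTC_COD": rng.choice(OUTCOME_CODES, size=len(ser_idx), p=OUTCOME_PROBS),
    })

    tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "THER": ther, "OUTC": outc}

    # Inject duplicates: re-report of an existing CASEID with later FDA_DT and
    # larger PRIMARYID; child rows are copied, so the survivor is equivalent.
    n_dup = int(round(config.duplicate_rate * n))
    duplicates = []
    if n_dup > 0:
        dup_report_idx = rng.choice(n, size=n_dup, replace=False)
        dup_pid = caseid[dup_report_idx] * 10 + 2
        dup_fda = fda_ord[dup_report_idx] + rng.integers(1, 91, size=n_dup)
        dup_demo = demo.iloc[dup_report_idx].copy()
        dup_demo["PRIMARYID"] = dup_pid.astype(str)
        dup_demo["FDA_DT"] = _dates(dup_fda)
        pid_map = dict(zip(primaryid[dup_report_idx].astype(str), dup_pid.astype(str)))
        for kind in ("DRUG", "REAC", "THER", "OUTC"):
            child = tables[kind]
            mask = child["PRIMARYID"].isin(pid_map)
            extra = child[mask].copy()
            extra["PRIMARYID"] = extra["PRIMARYID"].map(pid_map)
            tables[kind] = pd.concat([child, extra], ignore_index=True)
        tables["DEMO"] = pd.concat([demo, dup_demo], ignore_index=True)
        duplicates = [
            {"caseid": str(caseid[i]), "original_primaryid": str(primaryid[i]),
             "duplicate_primaryid": str(caseid[i] * 10 + 2)}
            for i in dup_report_idx
        ]

    expected_survivors = {str(c): str(c * 10 + 1) for c in caseid}
    for d in duplicates:
        expected_survivors[d["caseid"]] = d["duplicate_primaryid"]

    manifest = {
        "target_drug": config.target_drug,
        "planted_signals": [[ev, rr] for ev, rr in config.planted_signals],
        "event_vocabulary": vocab,
        "n_reports": n,
        "n_duplicates": n_dup,
        "duplicates": duplicates,
        "expected_survivors": expected_survivors,
        "onset_shape": config.onset_shape,
        "onset_scale": config.onset_scale,
        "seed": config.seed,
    }
    return SyntheticBundle(tables=tables, manifest=manifest)


def write_faers_dialect(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Write "$"-delimited quarterly-named ASCII files plus the manifest JSON.

    Missing values become empty fields between delimiters; the header row is
    uppercase. Round-trips losslessly through :func:`srsignal.ingest.read_table`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # Quarter tag from the end of the covered period, as in real archives.
    end = dt.date(2024, 9, 30)
    paths: dict[str, Path] = {}
    for kind, frame in bundle.tables.items():
        path = directory / f"{kind}{quarter_label(end)}.txt"
        frame.to_csv(path, sep="$", index=False, lineterminator="\n")
        paths[kind] = path
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=1))
    paths["MANIFEST"] = manifest_path
    return paths


def make_vigiaccess_aggregate(config: SyntheticConfig) -> pd.DataFrame:
    """Aggregate-only count table (category, stratum, count), the shape of a
    public interface that exposes distributions but no case-level records.

    Counts within each category sum to ``n_reports``; an "unknown" stratum
    absorbs configured missingness.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_reports
    rows: list[tuple[str, str, int]] = []

    sex = np.where(rng.random(n) < config.sex_split, "Female", "Male").astype(object)
    sex[rng.random(n) < config.missing_sex_rate] = "unknown"
    for label in ("Female", "Male", "unknown"):
        rows.append(("sex", label, int((sex == label).sum())))

    ages = rng.integers(18, 91, size=n)
    bins = [("< 18", 0, 17), ("18 - 44", 18, 44), ("45 - 64", 45, 64),
            ("65 - 74", 65, 74), (">= 75", 75, 200)]
    age_missing = rng.random(n) < config.missing_age_rate
    for label, lo, hi in bins:
        rows.append(("age_group", label, int(((ages >= lo) & (ages <= hi) & ~age_missing).sum())))
    rows.append(("age_group", "unknown", int(age_missing.sum())))

    years = np.array([dt.date.fromordinal(int(o)).year for o in
                      config.date_range[0].toordinal()
                      + rng.integers(0, config.date_range[1].toordinal()
                                     - config.date_range[0].toordinal() + 1, size=n)])
    for y in range(config.date_range[0].year, config.date_range[1].year + 1):
        rows.append(("year", str(y), int((years == y).sum())))

    continent = {"US": "Americas", "CA": "Americas", "BR": "Americas",
                 "JP": "Asia", "CN": "Asia", "KR": "Asia", "IN": "Asia",
                 "GB": "Europe", "FR": "Europe", "DE": "Europe", "IT": "Europe",
                 "AU": "Oceania"}
    region = np.array([continent[c] for c in rng.choice(COUNTRIES, size=n, p=COUNTRY_PROBS)])
    for label in ("Americas", "Asia", "Europe", "Oceania"):
        rows.append(("region", label, int((region == label).sum())))

    return pd.DataFrame(rows, columns=["category", "stratum", "count"])


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["date_range"] = [config.date_range[0].isoformat(), config.date_range[1].isoformat()]
    return d
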