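"""Baseline characterization of a report cohort: counts, percentages, sex
ratio, and distribution tables by sex, age group, year, region, reporter type
and seriousness — with "unknown" as a first-class stratum, since spontaneous
reporting data are heavily incomplete (age can be missing in most reports).

Rounding is half-up at the printed precision (2-decimal percents, 3-decimal
ratios), matching hand-tabulated baseline tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path

import pandas as pd

from ._util import round_half_up
from .ingest import SafetyReport

CATEGORIES = ("sex", "age_group", "year", "region", "reporter", "seriousness")

# Closed age intervals in years; anything not covered (or missing) is "unknown".
AGE_BINS_VIGIACCESS: list[tuple[str, float, float]] = [
    ("< 18", 0, 17), ("18 - 44", 18, 44), ("45 - 64", 45, 64),
    ("65 - 74", 65, 74), (">= 75", 75, float("inf")),
]
AGE_BINS_FAERS: list[tuple[str, float, float]] = [
    ("< 18", 0, 17), ("18 - 44", 18, 44), ("45 - 64", 45, 64),
    (">= 65", 65, float("inf")),
]

REPORTER_LABELS = {"MD": "Physician", "PH": "Pharmacist", "CN": "Consumer",
                   "OT": "Other health professional", "LW": "Lawyer",
                   "HP": "Health professional"}


@dataclass
class BaselineTable:
    """One category's distribution: rows of (stratum, count, percent)."""

    category: str
    rows: list[tuple[str, int, float]]
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["stratum", "count", "percent"]).assign(
            category=self.category)


def percentage(n: int, total: int) -> float:
    """Percent of ``total``, half-up to 2 decimals (e.g. 155 of 323 -> 47.99)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= n <= total:
        raise ValueError("n must lie in [0, total]")
    return round_half_up(Fraction(100 * n, total), 2)


def sex_ratio(male: int, female: int) -> float:
    """Male-to-female ratio, half-up to 3 decimals (e.g. 140:155 -> 0.903)."""
    if female <= 0:
        raise ValueError("female count must be positive")
    return round_half_up(Fraction(male, female), 3)


def load_region_map(path: str | Path | None = None) -> dict[str, str]:
    """Country -> continent lookup; ``None`` loads the bundled table."""
    if path is None:
        with resources.files("srsignal.data").joinpath("country_continent.csv").open() as fh:
            frame = pd.read_csv(fh, dtype=str)
    else:
        frame = pd.read_csv(path, dtype=str)
    return {str(c).strip().upper(): str(r).strip() for c, r in
            zip(frame["country"], frame["continent"])}


def _stratum(report: SafetyReport, category: str,
             age_bins: list[tuple[str, float, float]],
             region_map: dict[str, str]) -> str:
    if category == "sex":
        return {"F": "Female", "M": "Male"}.get(report.sex, "unknown")
    if category == "age_group":
        if report.age_years is None:
            return "unknown"
        for label, lo, hi in age_bins:
            if lo <= report.age_years <= hi:
                return label
        return "unknown"
    if category == "year":
        return str(report.fda_date.year)
    if category == "region":
        return region_map.get(report.country, "unknown") if report.country else "unknown"
    if category == "reporter":
        return REPORTER_LABELS.get(report.reporter, "unknown") if report.reporter else "unknown"
    if category == "seriousness":
        return "Serious" if report.serious else "Non-serious"
    raise ValueError(f"unknown category {category!r}")


def tabulate(
    reports: list[SafetyReport],
    category: str,
    age_bins: list[tuple[str, float, float]] | None = None,
    region_map: dict[str, str] | None = None,
) -> BaselineTable:
    """Distribution table over one category; counts sum to the cohort size and
    missing values land in the "unknown" stratum."""
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}, got {category!r}")
    if not reports:
        raise ValueError("cannot tabulate an empty cohort")
    age_bins = age_bins if age_bins is not None else AGE_BINS_VIGIACCESS
    region_map = region_map if region_map is not None else load_region_map()

    counts: dict[str, int] = {}
    for report in reports:
        label = _stratum(report, category, age_bins, region_map)
        counts[label] = counts.get(label, 0) + 1

    total = len(reports)

    def _order(label: str):
        return (label == "unknown", label)

    rows = [(label, counts[label], percentage(counts[label], total))
            for label in sorted(counts, key=_order)]
    return BaselineTable(category=category, rows=rows, total=total)


def tabulate_aggregate(aggregate: pd.DataFrame, category: str) -> BaselineTable:
    """Same table shape, computed from an aggregate-only count table
    (columns category, stratum, count) as exposed by public interfaces that
    publish distributions but no case-level records."""
    sub = aggregate[aggregate["category"] == category]
    if sub.empty:
        raise ValueError(f"category {category!r} not present in aggregate table")
    total = int(sub["count"].sum())
    rows = [(str(stratum), int(count), percentage(int(count), total))
            for stratum, count in zip(sub["stratum"], sub["count"])]
    return BaselineTable(category=category, rows=rows, total=total)
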