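"""Preferred-term -> system-organ-class mapping via a pluggable dictionary.

The full licensed MedDRA hierarchy cannot be redistributed; this module works
with any CSV of ``pt, pt_code, soc, soc_code`` rows and ships a ~60-term demo
stub covering the events the synthetic generator emits.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from ._util import normalize_name

UNMAPPED = "unmapped"


@dataclass
class MedDRADictionary:
    """PT-name lookup (normalized: trimmed, case-folded) to one primary SOC."""

    entries: dict[str, tuple[str, str, str]]  # norm PT -> (pt_code, soc, soc_code)

    def __len__(self) -> int:
        return len(self.entries)


def load_dictionary(path: str | Path | None = None) -> MedDRADictionary:
    """Load a dictionary CSV; ``None`` loads the bundled demo stub.

    Duplicate rows that agree collapse to one entry; duplicates that map the
    same PT to different SOCs are a data error and raise with the conflicts
    listed.
    """
    if path is None:
        with resources.files("srsignal.data").joinpath("meddra_stub.csv").open() as fh:
            frame = pd.read_csv(fh, dtype=str)
    else:
        frame = pd.read_csv(path, dtype=str)
    required = {"pt", "pt_code", "soc", "soc_code"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"dictionary CSV is missing column(s) {sorted(missing)}")

    entries: dict[str, tuple[str, str, str]] = {}
    conflicts = []
    for row in frame.itertuples(index=False):
        key = normalize_name(str(row.pt))
        value = (str(row.pt_code), str(row.soc).strip(), str(row.soc_code))
        if key in entries and entries[key][1] != value[1]:
            conflicts.append((row.pt, entries[key][1], value[1]))
        entries[key] = value if key not in entries else entries[key]
    if conflicts:
        listing = "; ".join(f"{pt!r}: {a!r} vs {b!r}" for pt, a, b in conflicts)
        raise ValueError(f"conflicting SOC assignments: {listing}")
    return MedDRADictionary(entries=entries)


def pt_to_soc(dictionary: MedDRADictionary, pt: str, log: dict | None = None) -> str:
    """SOC name for a PT, or the explicit "unmapped" bucket (counted in ``log``)."""
    entry = dictionary.entries.get(normalize_name(pt))
    if entry is None:
        if log is not None:
            log["unmapped_pts"] = log.get("unmapped_pts", 0) + 1
        return UNMAPPED
    return entry[1]
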