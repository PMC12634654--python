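"""Disproportionality signal detection with a planted tenfold risk.

One event (Myalgia) is planted at relative risk 10 given the target drug.
The four estimators are computed per event over 2x2 tables, and the
six-condition rule (a >= 3, PRR >= 2, chi2 >= 4, ROR CI low > 1, IC025 > 0,
EBGM05 > 2) decides which pairs are signals. Only the planted pair should
pass; every background event has relative risk 1.
"""

from srsignal import (SyntheticConfig, build_tables, compute_signals,
                      deduplicate, generate_bundle, link_reports,
                      primary_suspect_cohort, rank_signals)

config = SyntheticConfig(n_reports=20_000, seed=11,
                         planted_signals=[("Myalgia", 10.0)])
t = generate_bundle(config).tables
reports = link_reports(deduplicate(t["DEMO"]), t["DRUG"], t["REAC"],
                       t["THER"], t["OUTC"],
                       target_drug_names=[config.target_drug])
cohort, background = primary_suspect_cohort(reports, [config.target_drug])
tables = build_tables(cohort, background, level="PT")
rows = compute_signals(tables)

print(f"{'event':12s} {'a':>4s} {'ROR':>7s} {'PRR':>6s} {'chi2':>8s} "
      f"{'IC025':>6s} {'EBGM05':>7s}  signal")
for row in rank_signals(rows, by="ror", k=5):
    print(f"{row.event:12s} {row.table.a:4d} {row.ror:7.2f} {row.prr:6.2f} "
          f"{row.chi2:8.1f} {row.ic025:6.2f} {row.ebgm05:7.2f}  {row.signal}")
flagged = [r.event for r in rows if r.signal]
print(f"\nflagged: {flagged} (planted: Myalgia at RR = 10; a ROR near 10 with "
      "all six thresholds met is a detected signal)")
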