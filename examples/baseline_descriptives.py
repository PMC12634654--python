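"""Baseline characterization of a target-drug cohort.

Builds a small synthetic bundle, extracts the cohort where the target drug
is the primary suspect, and prints distribution tables (count, percent) for
sex and age group. "unknown" is a first-class stratum: spontaneous reports
are heavily incomplete, and percentages are over the whole cohort.
"""

from srsignal import (SyntheticConfig, deduplicate, generate_bundle,
                      link_reports, primary_suspect_cohort, sex_ratio,
                      tabulate)

config = SyntheticConfig(n_reports=5000, seed=11)
tables = generate_bundle(config).tables
reports = link_reports(deduplicate(tables["DEMO"]), tables["DRUG"],
                       tables["REAC"], tables["THER"], tables["OUTC"],
                       target_drug_names=[config.target_drug])
cohort, _ = primary_suspect_cohort(reports, [config.target_drug])
print(f"cohort: {len(cohort)} reports with {config.target_drug} as primary suspect\n")

for category in ("sex", "age_group"):
    table = tabulate(cohort, category)
    print(category)
    for stratum, count, percent in table.rows:
        print(f"  {stratum:10s} {count:5d}  {percent:6.2f}%")

counts = {r[0]: r[1] for r in tabulate(cohort, "sex").rows}
print(f"\nmale-to-female ratio: {sex_ratio(counts['Male'], counts['Female'])}:1")
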