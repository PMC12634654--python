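"""Generate a synthetic spontaneous-report bundle with planted ground truth.

Writes the five "$"-delimited case-level tables (DEMO, DRUG, REAC, THER,
OUTC) plus a manifest recording every planted drug-event association and
every injected duplicate, so downstream analyses can be validated exactly.
"""

from srsignal import SyntheticConfig, generate_bundle, write_faers_dialect

config = SyntheticConfig(
    n_reports=5000,
    seed=11,
    planted_signals=[("Myalgia", 10.0), ("Gout", 4.0)],
    duplicate_rate=0.05,
)
bundle = generate_bundle(config)
paths = write_faers_dialect(bundle, "scratch/bundle")

for kind, frame in bundle.tables.items():
    print(f"{kind:5s} {len(frame):6d} rows -> {paths[kind]}")
print(f"planted signals: {bundle.manifest['planted_signals']}")
print(f"injected duplicates: {bundle.manifest['n_duplicates']} "
      "(re-reports of an existing case with a later receipt date)")
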