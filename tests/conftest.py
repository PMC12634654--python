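import pytest

import srsignal as s


@pytest.fixture(scope="session")
def planted_config():
    return s.SyntheticConfig(n_reports=2000, seed=7,
                             planted_signals=[("Myalgia", 10.0)])


@pytest.fixture(scope="session")
def planted_bundle(planted_config):
    return s.generate_bundle(planted_config)


@pytest.fixture(scope="session")
def linked_cohort(planted_bundle, planted_config):
    """(cohort, background) from the planted bundle, run through the full
    dedup/link/cohort path."""
    t = planted_bundle.tables
    demo = s.deduplicate(t["DEMO"])
    reports = s.link_reports(demo, t["DRUG"], t["REAC"], t["THER"], t["OUTC"],
                             target_drug_names=[planted_config.target_drug])
    return s.primary_suspect_cohort(reports, [planted_config.target_drug])


def run_to_signals(config):
    """Generate a bundle and run it in memory through dedup, linking, cohort
    extraction and the four estimators; returns the signal rows."""
    bundle = s.generate_bundle(config)
    t = bundle.tables
    demo = s.deduplicate(t["DEMO"])
    reports = s.link_reports(demo, t["DRUG"], t["REAC"], t["THER"], t["OUTC"],
                             target_drug_names=[config.target_drug])
    cohort, background = s.primary_suspect_cohort(reports, [config.target_drug])
    tables = s.build_tables(cohort, background)
    return s.compute_signals(tables)
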