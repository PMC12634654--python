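"""End-to-end orchestration: ingest -> describe -> signals -> time-to-onset
-> sex-stratified comparison, from one declarative config, with a
machine-readable run report (a funnel of counts: rows read -> deduplicated
-> cohort -> TTO-evaluable, plus every exclusion)."""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import descriptives, disproportionality, ingest, meddra, synthetic, tto
from .descriptives import AGE_BINS_FAERS, AGE_BINS_VIGIACCESS

logger = logging.getLogger("srsignal")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-loadable."""

    input_dir: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    target_drug_names: list[str] = field(default_factory=lambda: ["FENOFIBRIC ACID"])
    role_code: str = "PS"
    dictionary_path: str | None = None  # None -> bundled stub
    age_bin_scheme: str = "vigiaccess"  # "vigiaccess" | "faers"
    thresholds: disproportionality.SignalThresholds = field(
        default_factory=disproportionality.SignalThresholds)
    ic_method: str = "moment"
    ror_continuity: bool = False
    yates: bool = True
    stratify_by_sex: bool = True
    output_dir: str = "srsignal_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dir is None and self.synthetic is None:
            raise ValueError("config needs either input_dir or a synthetic block")
        if self.age_bin_scheme not in ("vigiaccess", "faers"):
            raise ValueError("age_bin_scheme must be 'vigiaccess' or 'faers'")

    @property
    def age_bins(self):
        return AGE_BINS_VIGIACCESS if self.age_bin_scheme == "vigiaccess" else AGE_BINS_FAERS


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        syn = dict(raw["synthetic"])
        if "date_range" in syn:
            syn["date_range"] = tuple(dt.date.fromisoformat(d) for d in syn["date_range"])
        if "planted_signals" in syn:
            syn["planted_signals"] = [tuple(p) for p in syn["planted_signals"]]
        raw["synthetic"] = synthetic.SyntheticConfig(**syn)
    if "thresholds" in raw and raw["thresholds"] is not None:
        raw["thresholds"] = disproportionality.SignalThresholds(**raw["thresholds"])
    return RunConfig(**raw)


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            report.setdefault("stages", {})[name] = round(elapsed, 3)
            if exc_type is not None:
                logger.error("stage %s: FAILED after %.2fs (%s)", name, elapsed, exc)
            else:
                logger.info("stage %s: done in %.2fs", name, elapsed)
            return False
    return _Timer()


def signals_to_frame(rows: list[disproportionality.SignalRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        records.append({
            "level": r.level, "event": r.event,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "n": r.table.n, "expected": r.table.expected,
            "ror": r.ror, "ror_low": r.ror_low, "ror_high": r.ror_high,
            "prr": r.prr, "chi2": r.chi2, "ic": r.ic, "ic025": r.ic025,
            "ebgm": r.ebgm, "ebgm05": r.ebgm05, "signal": r.signal,
        })
    return pd.DataFrame(records)


def forest_frame(rows: list[disproportionality.SignalRow]) -> pd.DataFrame:
    """Forest-plot-ready export: one (estimate, low, high) row per event."""
    return pd.DataFrame([{"event": r.event, "estimate": r.ror,
                          "low": r.ror_low, "high": r.ror_high} for r in rows])


def baseline_frames(tables: list[descriptives.BaselineTable]) -> pd.DataFrame:
    return pd.concat([t.to_frame() for t in tables], ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write CSV/JSON outputs under ``config.output_dir``.

    Returns the run report (funnel counts, stage timings, output paths).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"funnel": {}, "exclusions": {}, "outputs": {}}
    log: dict = {}

    with _stage(report, "ingest"):
        if config.input_dir is not None:
            tables = ingest.load_bundle_dir(config.input_dir, log=log)
        else:
            bundle = synthetic.generate_bundle(config.synthetic)
            tables = bundle.tables
            report["synthetic_manifest"] = {
                k: v for k, v in bundle.manifest.items()
                if k not in ("expected_survivors", "duplicates")}
        report["funnel"]["demo_rows_read"] = int(len(tables["DEMO"]))
        demo = ingest.deduplicate(tables["DEMO"])
        report["funnel"]["after_dedup"] = int(len(demo))
        reports = ingest.link_reports(
            demo, tables["DRUG"], tables["REAC"], tables["THER"], tables["OUTC"],
            target_drug_names=config.target_drug_names, log=log)
        report["funnel"]["linked_reports"] = len(reports)
        cohort, background = ingest.primary_suspect_cohort(
            reports, config.target_drug_names, role_code=config.role_code)
        report["funnel"]["cohort"] = len(cohort)
        report["funnel"]["background"] = len(background)
        if not cohort:
            raise RuntimeError("empty cohort: no report carries the target drug "
                               "in the primary-suspect role")

    with _stage(report, "describe"):
        region_map = descriptives.load_region_map()
        baselines = [descriptives.tabulate(cohort, cat, age_bins=config.age_bins,
                                           region_map=region_map)
                     for cat in descriptives.CATEGORIES]
        baseline = baseline_frames(baselines)
        path = out / "baseline.csv"
        baseline.to_csv(path, index=False, float_format="%.2f")
        report["outputs"]["baseline"] = str(path)

    with _stage(report, "signals"):
        dictionary = meddra.load_dictionary(config.dictionary_path)
        all_rows = []
        prior = None
        for level in ("PT", "SOC"):
            ctables = disproportionality.build_tables(
                cohort, background, level=level, dictionary=dictionary)
            if prior is None:
                # The shrinkage prior describes the whole report collection;
                # fit it once on the (larger) PT-level table set and reuse it
                # for the SOC roll-up.
                prior = disproportionality.fit_gps_prior(ctables)
            rows = disproportionality.compute_signals(
                ctables, level=level, prior=prior, thresholds=config.thresholds,
                ror_continuity=config.ror_continuity, yates=config.yates,
                ic_method=config.ic_method)
            all_rows.extend(rows)
        frame = signals_to_frame(all_rows)
        path = out / "signals.csv"
        frame.to_csv(path, index=False, float_format="%.3f")
        report["outputs"]["signals"] = str(path)
        flagged = frame[frame["signal"]]
        path = out / "signals_flagged.csv"
        flagged.to_csv(path, index=False, float_format="%.3f")
        report["outputs"]["signals_flagged"] = str(path)
        path = out / "forest_pt.csv"
        forest_frame([r for r in all_rows if r.level == "PT" and r.signal]).to_csv(
            path, index=False, float_format="%.3f")
        report["outputs"]["forest_pt"] = str(path)
        report["funnel"]["pt_pairs"] = int((frame["level"] == "PT").sum())
        report["funnel"]["flagged_pairs"] = int(frame["signal"].sum())

    with _stage(report, "tto"):
        sample = tto.compute_tto(cohort)
        report["funnel"]["tto_evaluable"] = sample.n
        report["exclusions"]["tto_missing_dates"] = sample.n_excluded_missing
        report["exclusions"]["tto_negative"] = sample.n_excluded_negative
        tto_result: dict = {"n": sample.n}
        if sample.n >= 10 and not math.isclose(float(sample.values.std()), 0.0):
            fit = tto.fit_weibull(sample)
            med, lo, hi = tto.median_ci_normal(sample)
            curve = tto.cumulative_incidence(sample)
            tto_result.update({
                "weibull_shape": fit.shape, "weibull_shape_ci": list(fit.shape_ci),
                "weibull_scale": fit.scale, "weibull_scale_ci": list(fit.scale_ci),
                "failure_class": fit.failure_class,
                "median": med, "median_ci_normal": [lo, hi],
                "median_ci_note": "normal approximation; lower bound may be negative",
                "iqr": list(curve["iqr"]),
            })
            hist = tto.monthly_histogram(sample)
            pd.DataFrame(hist, columns=["month", "count", "percent"]).to_csv(
                out / "tto_monthly.csv", index=False)
            pd.DataFrame(curve["curve"], columns=["day", "cumulative_percent"]).to_csv(
                out / "tto_cumulative.csv", index=False, float_format="%.2f")
            report["outputs"]["tto_monthly"] = str(out / "tto_monthly.csv")
            report["outputs"]["tto_cumulative"] = str(out / "tto_cumulative.csv")
        report["tto"] = tto_result

    if config.stratify_by_sex:
        with _stage(report, "sex_comparison"):
            females = [r for r in cohort if r.sex == "F"]
            males = [r for r in cohort if r.sex == "M"]
            sf, sm = tto.compute_tto(females), tto.compute_tto(males)
            if sf.n >= 2 and sm.n >= 2:
                comp = tto.compare_strata(sf, sm)
                report["sex_comparison"] = {
                    "n_female": sf.n, "n_male": sm.n,
                    "median_female": comp["median_a"], "iqr_female": list(comp["iqr_a"]),
                    "median_male": comp["median_b"], "iqr_male": list(comp["iqr_b"]),
                    "wilcoxon_p": comp["p_value"],
                }
            else:
                report["sex_comparison"] = {"n_female": sf.n, "n_male": sm.n,
                                            "note": "too few onset times per stratum"}

    report["exclusions"].update(log)
    path = out / "run_report.json"
    path.write_text(json.dumps(report, indent=1, default=str))
    report["outputs"]["run_report"] = str(path)
    return report


def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.synthetic is not None:
        d["synthetic"] = synthetic.config_to_dict(config.synthetic)
    return d
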