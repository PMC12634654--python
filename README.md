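# srsignal

Signal detection and time-to-onset modelling for spontaneous adverse-event
reporting data, aimed at pharmacovigilance analysts who work with
FAERS-style quarterly extracts (case-level `$`-delimited DEMO / DRUG / REAC /
THER / OUTC tables) or aggregate-only count tables of the kind public
interfaces such as VigiAccess expose.

Spontaneous reporting systems have no at-risk denominator, so drug safety
signals are found by *disproportionality*: comparing how often a drug and an
event are reported together against what independence within the database
would predict. For each (drug, event) pair a 2×2 table is formed over
deduplicated reports —

|                        | event | other events |
|------------------------|-------|--------------|
| target drug (primary suspect) | a | b |
| all other drugs        | c     | d            |

with N = a+b+c+d and E = (a+b)(a+c)/N — and four estimators are computed:

- **ROR** = (a·d)/(b·c), with a Wald 95% CI on the log scale;
- **PRR** = [a/(a+b)] / [c/(c+d)], with a Yates-corrected χ² statistic;
- **IC** (BCPNN) = posterior mean of log₂ p(drug,event)/(p(drug)·p(event))
  under independent beta posteriors, with IC025 = mean − 2·sd computed from
  exact log-beta moments (digamma/trigamma);
- **EBGM** (gamma-Poisson shrinker): a ~ Poisson(λE) with a two-component
  gamma mixture prior on λ fitted across all tables by maximizing the
  negative-binomial marginal likelihood; EBGM = exp E[ln λ | a] and EBGM05
  is the posterior 5th percentile.

A pair is a **signal** only when six conditions hold jointly:
a ≥ 3, PRR ≥ 2, χ² ≥ 4, ROR CI lower bound > 1, IC025 > 0, EBGM05 > 2.
The conjunction is the false-positive control.

Onset dynamics are modelled by fitting a Weibull distribution to
time-to-onset (event date − therapy start, in days): shape β < 1 is an
"early failure" profile (risk concentrated just after initiation), β ≈ 1
a constant hazard, β > 1 "wear-out". The package also produces monthly
onset histograms, cumulative-incidence curves, median onset with a
normal-approximation CI, and a sex-stratified Wilcoxon rank-sum comparison.

A first-class synthetic-data generator emulates the FAERS dialect with
planted ground truth (relative-risk structure, injected duplicate case
reports, Weibull onset times, configurable missingness), so the entire
pipeline is testable without any database download.

## Worked example

```python
from srsignal import (SyntheticConfig, build_tables, compute_signals,
                      deduplicate, generate_bundle, link_reports,
                      primary_suspect_cohort)

config = SyntheticConfig(n_reports=20_000, seed=11,
                         planted_signals=[("Myalgia", 10.0)])
t = generate_bundle(config).tables
reports = link_reports(deduplicate(t["DEMO"]), t["DRUG"], t["REAC"],
                       t["THER"], t["OUTC"],
                       target_drug_names=[config.target_drug])
cohort, background = primary_suspect_cohort(reports, [config.target_drug])
rows = compute_signals(build_tables(cohort, background, level="PT"))
```

Running `python examples/signal_detection.py` (the same computation) prints:

```
event           a     ROR    PRR     chi2  IC025  EBGM05  signal
Myalgia       409   17.42   9.93   2288.3   2.56    6.75  True
Fatigue        57    1.45   1.42      6.5   0.05    0.89  False
Rash           51    1.27   1.26      2.3  -0.14    0.86  False
...
flagged: ['Myalgia']
```

Myalgia was planted at relative risk 10: its PRR (a risk-ratio-like
quantity) lands near 10, all six thresholds are met, and it is the only
flagged pair — every background event has relative risk 1 and stays below
at least one threshold. `python examples/time_to_onset.py` fits the onset
model on the same cohort:

```
Weibull shape 0.70 (95% CI 0.67-0.73), scale 44.2 d -> early failure profile
median onset 25.0 d, normal-approximation 95% CI [22.2, 27.8]
  month 1: 651 cases (53.94%)
```

recovering the generating shape 0.68 (early-failure: risk is highest in the
first months of therapy). The other examples cover bundle simulation
(`examples/simulate_bundle.py`) and baseline descriptive tables
(`examples/baseline_descriptives.py`).

A thin CLI wraps the same pipeline:

```sh
srsignal simulate --n-reports 20000 --seed 11 --plant 'Myalgia:10' --out bundle/
srsignal signals --input-dir bundle/ --drug 'FENOFIBRIC ACID' --out results/
srsignal run-all --config run.yaml
```

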