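# Methods

## Data model and deduplication

The package operates on case-level spontaneous reports in the FAERS quarterly
ASCII dialect: one `$`-delimited file per table (DEMO, DRUG, REAC, THER,
OUTC) with an uppercase header, empty fields for missing values, and dates as
8-, 6- or 4-digit strings. Partial dates follow a fixed imputation policy:
`YYYYMM` is read as the first of the month (acceptable for monthly onset
bins), `YYYY` contributes to annual tabulations but is unusable for onset
intervals, and anything unparseable is missing.

Because the same case is re-reported across quarters, reports are grouped by
CASEID and only one survives: the row with the most recent FDA receipt date
(FDA_DT), ties broken by the largest PRIMARYID. The rule is idempotent and
its output is sorted by CASEID for determinism. Reports without any reaction
row are dropped and counted; every exclusion anywhere in the pipeline lands
in the run report's funnel.

Cohort extraction matches drug names after trimming, whitespace collapsing
and uppercasing, against a user-extendable synonym list, and requires the
primary-suspect role code (`PS` by default, configurable). Seriousness is
case-level: a report is serious iff it has at least one outcome row.

## Disproportionality estimators

All statistics are computed from per-event 2×2 tables in which `a` counts
*distinct* reports (one contribution per event per report; at SOC level one
contribution per SOC per report, however many of its PTs map there — the
event-level alternative is a flag). The comparator is every report whose
primary suspect is another drug, so all tables share N.

- **ROR** with Wald CI: exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). Zero cells
  yield NaN (flagged, never a signal) unless the optional Haldane 0.5
  continuity correction is enabled; it is off by default because the signal
  rule already requires a ≥ 3.
- **PRR** with Yates-corrected χ² = N(|ad−bc|−N/2)²/[(a+b)(c+d)(a+c)(b+d)],
  floored at 0; the correction is the convention behind the "χ² ≥ 4"
  threshold and can be disabled.
- **BCPNN IC**: the posterior of IC = log₂ p11/(p1·p·1) under independent
  beta posteriors with hyperparameters α1 = β1 = γ11 = 1, α = β = 2 and γ
  chosen so the prior IC expectation is ≈ 0. Mean and variance use the exact
  log-beta moments (digamma/trigamma), so the estimate matches Monte-Carlo
  draws from the same posterior; IC025 = mean − 2·sd. Note the exact
  posterior mean is slightly negative at very small counts even when a = E
  (≈ −1/(2(a+1)ln 2) bits) — a property of E[log x], not a bug. The simpler
  shrinkage variant IC = log₂((a+0.5)/(E+0.5)) is available via
  `ic_method="shrinkage"`.
- **Gamma-Poisson shrinker**: a ~ Poisson(λE), λ ~ p·Gamma(α₁,β₁) +
  (1−p)·Gamma(α₂,β₂). The prior is fitted across the whole table collection
  by maximizing the mixture-of-negative-binomials marginal likelihood in
  transformed (log/logit) parameters from the conventional start
  (0.2, 0.1, 2, 4, 1/3), using L-BFGS-B within bounds with a Nelder-Mead
  polish if the line search stalls; per-table log-likelihoods are sorted
  before summation so the fit is bit-identical under permutation of the
  input tables. The posterior is the conjugate mixture
  Gamma(αⱼ+a, βⱼ+E) with evidence-updated weights; EBGM = exp E[ln λ|a]
  (geometric mean) and EBGM05 is found by Brent root-finding on the mixture
  CDF (relative tolerance 1e−6, with adaptive bracketing because a
  near-zero fitted shape can pile posterior mass at 0). In the pipeline the
  prior is fitted once on PT-level tables and reused for the SOC roll-up:
  the prior describes the report collection, not one aggregation level.

The six-condition signal rule (a ≥ 3, PRR ≥ 2, χ² ≥ 4, ROR CI low > 1,
IC025 > 0, EBGM05 > 2) is a conjunction; NaN statistics never signal. Every
threshold is configurable. No multiplicity correction is applied on top —
the conjunction is the false-positive control, and under a pure-null
synthetic database it flags well under 5% of pairs with a ≥ 3.

## Time-to-onset model

TTO = event date − therapy start, in whole days; negative intervals and
reports missing either date are excluded (and counted), zero is kept.
The Weibull fit maximizes the complete-sample likelihood via Newton
iteration on the profile shape equation
Σxᵏln x/Σxᵏ − 1/k − mean(ln x) = 0 (initialized at 1.2/sd(ln x)), with the
scale in closed form given the shape. Zeros enter the likelihood as 0.5 day
(log of zero is undefined) but are retained as zeros for medians and IQRs.
Standard errors come from the inverse observed information (central finite
differences of the log-likelihood); 95% CIs are estimate ± 1.96·SE on the
natural scale — the natural rather than log scale is used because the
reported-interval convention in this field is symmetric about the point
estimate. The parametric median is scale·(ln 2)^{1/β} with a delta-method
CI. Failure classification: β within ±0.05 of 1 is "random", below is
"early", above is "wear-out".

The nonparametric median CI uses SE = 1/(2·f̂(median)·√n) with f̂ a Gaussian
KDE; the lower bound is reported unclipped and can be negative near the
boundary — an artifact of the normal approximation that is kept (with a
note field) because it is the convention this output mirrors. Monthly
histograms use 30-day half-open bins [30(m−1), 30m). The sex-stratified
comparison is a two-sided Wilcoxon rank-sum (Mann-Whitney) test with tie
correction under the normal approximation; no survival weighting, since
complete samples are assumed throughout (spontaneous reports carry no
at-risk denominator, so no censoring model is meaningful).

## Synthetic-data generator

The generator emulates the study conditions of a single-drug safety profile
over a 2004Q1–2024Q3 reporting window. Defaults: 5,000 reports per bundle;
target-drug (primary-suspect) rate 0.05; 50 background PTs each assigned
independently per report with probability 0.04 (≈ 2 events per report, the
density typical of such databases); onset times Weibull(shape 0.68, scale
45 d) — an early-failure profile; serious fraction 0.17; missing age 0.70,
missing sex 0.23, missing therapy-start 0.30; duplicate rate 0.05. Planted
signals multiply the event probability given the target drug by the
configured relative risk (configurations pushing any probability past 1 are
rejected). Duplicates are injected as a later-FDA_DT re-report of an
existing CASEID with a larger PRIMARYID and copied child rows, so the
expected deduplication survivor is recorded in the manifest. Dates are full
`YYYYMMDD`; a configurable fraction of event dates can be truncated to
month or year precision to stress the partial-date policy.

What the generator does *not* emulate — and hence what green tests do not
show about real data: drug-name misspellings and synonym noise, report-level
correlation between events (assignment is independent Bernoulli per PT),
indication confounding, reporting-rate drift over calendar time, and
database-scale heterogeneity of the background. Planted-recovery results
demonstrate the estimators and the rule, not real-database operating
characteristics.

The aggregate count table mirrors interfaces that publish only per-category
distributions (sex, age group, year, region): counts per category sum to
the report total, with an "unknown" stratum absorbing missingness; no
case-level comparator can be derived from it, so disproportionality on the
aggregate path requires user-supplied database totals.

## Descriptive conventions

Percentages are half-up at 2 decimals over the whole cohort (including
unknown strata); sex ratios half-up at 3 decimals. Two age-bin schemes are
bundled (one with 65–74 / ≥ 75 splits, one with a single ≥ 65 bin) and any
list of closed intervals is accepted. Regions come from a bundled
country→continent CSV; unknown countries map to "unknown".

## Problem sizes and numerical choices

The test suite exercises planted-signal recovery at 50,000 reports × 20
seeds and null calibration at 5,000 reports × 20 seeds; Weibull recovery
checks use n = 2,000 across 20 seeds per shape in {0.5, 0.68, 1, 1.5} (mean
fitted shape within 2%, CI coverage ≥ 18/20). The acceptance script refits
the shape on 5,000 draws, where the asymptotic SE of the shape MLE is
≈ 0.68·√(0.608/n) ≈ 0.008. EBGM/EBGM05 are validated against direct
numerical integration of the posterior (60,000-point log grid) to within
1%, and the BCPNN IC against 10⁵ Monte-Carlo posterior draws.

## Known limitations

- The deduplication rule assumes numeric PRIMARYIDs (FAERS convention);
  non-numeric ids fall back to NaN ordering.
- SOC-level analysis is only as good as the supplied dictionary; the
  bundled ~60-term stub exists for demonstration and testing, not for
  production coding (real MedDRA is licensed).
- The aggregate-table path supports descriptives only.
- No stratified or regression-adjusted disproportionality, and no
  legacy (pre-2012Q4) ISR-era schema support.
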