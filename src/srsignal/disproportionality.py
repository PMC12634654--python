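"""Disproportionality statistics for drug-event pairs in spontaneous reports.

For each event (at PT or SOC level) a 2x2 table is formed over deduplicated
reports:

    =============================  ==========  ============
    ..                             event       other events
    =============================  ==========  ============
    target drug (primary suspect)  a           b
    all other drugs                c           d
    =============================  ==========  ============

with N = a+b+c+d and E = (a+b)(a+c)/N the count expected under independence.
Four estimators are computed:

* ROR, the reporting odds ratio (a*d)/(b*c), with a Wald 95% CI on the log
  scale;
* PRR, the proportional reporting ratio [a/(a+b)] / [c/(c+d)], accompanied by
  a Yates-corrected chi-square statistic;
* the Bayesian information component IC = log2 p(drug,event)/(p(drug)p(event))
  under independent beta posteriors (BCPNN), with IC025 = mean - 2 sd;
* EBGM, the empirical-Bayes geometric mean of the Poisson rate multiplier
  lambda under a two-component gamma mixture prior fitted to the whole table
  collection (gamma-Poisson shrinker), with EBGM05 its posterior 5th
  percentile.

A pair is a *signal* when six conditions hold jointly: a >= 3, PRR >= 2,
chi-square >= 4, ROR CI lower bound > 1, IC025 > 0 and EBGM05 > 2. The
conjunction is the false-positive control; no multiplicity correction is
applied on top of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import digamma, logsumexp, polygamma

from .ingest import SafetyReport
from .meddra import MedDRADictionary, pt_to_soc

Z975 = 1.959963984540054


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected co-report count under independence, (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass
class SignalThresholds:
    """The six-condition signal rule; defaults are the conventional cut-offs."""

    min_count: int = 3
    min_prr: float = 2.0
    min_chi2: float = 4.0
    min_ror_low: float = 1.0   # strict: ror_low must exceed this
    min_ic025: float = 0.0     # strict
    min_ebgm05: float = 2.0    # strict


@dataclass
class GPSPrior:
    """Two-component gamma mixture prior on the rate multiplier lambda."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_p: float
    converged: bool = True
    log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma parameters must be positive")
        if not 0.0 <= self.mix_p <= 1.0:
            raise ValueError("mix_p must be in [0, 1]")


@dataclass
class SignalRow:
    event: str
    level: str  # "PT" | "SOC"
    table: ContingencyTable
    ror: float = math.nan
    ror_low: float = math.nan
    ror_high: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    signal: bool = False
    extra: dict = field(default_factory=dict)


def _distinct_events(report: SafetyReport, level: str,
                     dictionary: MedDRADictionary | None) -> set[str]:
    if level == "PT":
        return set(report.reactions)
    if level == "SOC":
        if dictionary is None:
            raise ValueError("SOC-level tables require a dictionary")
        # One contribution per SOC per report, however many of its PTs map there.
        return {pt_to_soc(dictionary, pt) for pt in report.reactions}
    raise ValueError(f"level must be 'PT' or 'SOC', got {level!r}")


def build_tables(
    cohort: list[SafetyReport],
    background: list[SafetyReport],
    level: str = "PT",
    dictionary: MedDRADictionary | None = None,
) -> dict[str, ContingencyTable]:
    """One 2x2 table per event; ``a`` counts distinct cohort reports
    mentioning the event, so every table shares the same N."""
    if not background:
        raise ValueError("background (comparator) reports are required")
    a_counts: dict[str, int] = {}
    c_counts: dict[str, int] = {}
    for report in cohort:
        for ev in _distinct_events(report, level, dictionary):
            a_counts[ev] = a_counts.get(ev, 0) + 1
    for report in background:
        for ev in _distinct_events(report, level, dictionary):
            c_counts[ev] = c_counts.get(ev, 0) + 1
    n_cohort, n_background = len(cohort), len(background)
    tables = {}
    for ev in sorted(set(a_counts) | set(c_counts)):
        a = a_counts.get(ev, 0)
        c = c_counts.get(ev, 0)
        tables[ev] = ContingencyTable(a=a, b=n_cohort - a, c=c, d=n_background - c)
    return tables


def ror(table: ContingencyTable, continuity: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI; a zero cell yields NaN unless
    the optional Haldane 0.5 continuity correction is enabled."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        if not continuity:
            return (math.nan, math.nan, math.nan)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (estimate, estimate * math.exp(-Z975 * se), estimate * math.exp(Z975 * se))


def prr(table: ContingencyTable, yates: bool = True) -> tuple[float, float]:
    """Proportional reporting ratio and (by default Yates-corrected)
    chi-square. ``a = 0`` gives PRR 0; a zero margin gives NaN."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if a + b == 0 or c + d == 0 or c == 0:
        return (math.nan, math.nan)
    estimate = (a / (a + b)) / (c / (c + d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return (estimate, math.nan)
    diff = abs(a * d - b * c) - (n / 2 if yates else 0)
    chi2 = n * max(diff, 0.0) ** 2 / denom
    return (estimate, chi2)


def bcpnn_ic(table: ContingencyTable, method: str = "moment") -> tuple[float, float]:
    """Information component and its lower bound IC025 = E[IC] - 2 sd[IC].

    ``method="moment"``: posterior mean and variance of
    IC = log2 p11/(p1. p.1) under independent beta posteriors
    p11 ~ Beta(g11 + a, g - g11 + N - a), p1. ~ Beta(a1 + n1., A - a1 + N - n1.),
    p.1 ~ Beta(b1 + n.1, B - b1 + N - n.1) with a1 = b1 = g11 = 1, A = B = 2
    and g chosen so the prior IC expectation is ~0; the log-beta moments are
    exact (digamma/trigamma), so the estimate agrees with Monte-Carlo draws
    from the same posterior.

    ``method="shrinkage"``: the simpler IC = log2((a+0.5)/(E+0.5)) with the
    same credible-interval construction applied on a normal approximation.
    """
    a, n = table.a, table.n
    n1 = table.a + table.b
    n2 = table.a + table.c
    if method == "shrinkage":
        e = table.expected
        ic = math.log2((a + 0.5) / (e + 0.5))
        sd = math.sqrt(1 / (a + 0.5) + 1 / (e + 0.5)) / math.log(2)
        return (ic, ic - 2 * sd)
    if method != "moment":
        raise ValueError(f"unknown BCPNN method {method!r}")

    a1 = b1 = g11 = 1.0
    big_a = big_b = 2.0
    g = g11 * (n + big_a) * (n + big_b) / ((n1 + a1) * (n2 + b1))
    ln2 = math.log(2)
    mean = (
        digamma(a + g11) - digamma(n + g)
        - (digamma(n1 + a1) - digamma(n + big_a))
        - (digamma(n2 + b1) - digamma(n + big_b))
    ) / ln2
    trig = polygamma(1, [a + g11, n + g, n1 + a1, n + big_a, n2 + b1, n + big_b])
    var = (trig[0] - trig[1] + trig[2] - trig[3] + trig[4] - trig[5]) / ln2**2
    return (float(mean), float(mean - 2 * math.sqrt(max(var, 0.0))))


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    # Marginal of a ~ Poisson(lambda E), lambda ~ Gamma(alpha, rate beta):
    # negative binomial with size alpha and success prob beta/(beta+E).
    return stats.nbinom.logpmf(a, alpha, beta / (beta + e))


_PARAM_BOUNDS = np.array([[-10.0, 10.0]] * 4 + [[-8.0, 8.0]])


def _mixture_loglik(params: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    params = np.clip(params, _PARAM_BOUNDS[:, 0], _PARAM_BOUNDS[:, 1])
    la1, lb1, la2, lb2, t = params
    alpha1, beta1, alpha2, beta2 = np.exp([la1, lb1, la2, lb2])
    log_p = -np.logaddexp(0.0, -t)      # log sigmoid(t)
    log_1mp = -np.logaddexp(0.0, t)
    comp = np.stack([
        log_p + _nb_logpmf(a, alpha1, beta1, e),
        log_1mp + _nb_logpmf(a, alpha2, beta2, e),
    ])
    per_table = logsumexp(comp, axis=0)
    # Sort before summing so the result is bit-identical under permutation
    # of the input tables.
    return float(np.sum(np.sort(per_table)))


def fit_gps_prior(
    tables: list[ContingencyTable] | dict[str, ContingencyTable],
    init: tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1 / 3),
) -> GPSPrior:
    """Fit the two-component gamma mixture by maximizing the summed negative
    binomial marginal log-likelihood of the observed counts ``a`` given the
    expected counts ``E``."""
    if isinstance(tables, dict):
        tables = list(tables.values())
    pairs = sorted((t.a, t.expected) for t in tables if t.expected > 0)
    if len(pairs) < 20:
        raise ValueError(f"need >= 20 tables with E > 0 to fit the prior, got {len(pairs)}")
    a = np.array([p[0] for p in pairs], dtype=float)
    e = np.array([p[1] for p in pairs], dtype=float)
    if a.max() == 0:
        raise ValueError("degenerate data: every table has a = 0")

    a1, b1, a2, b2, p = init
    x0 = np.array([math.log(a1), math.log(b1), math.log(a2), math.log(b2),
                   math.log(p / (1 - p))])
    # L-BFGS-B on transformed (log / logit) parameters; bounds keep the
    # weakly identified directions (e.g. an unused second component) from
    # drifting to overflow.
    objective = lambda x: -_mixture_loglik(x, a, e)  # noqa: E731
    result = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=list(map(tuple, _PARAM_BOUNDS)),
        options={"maxiter": 2000, "maxfun": 20000},
    )
    if not result.success:
        # The marginal likelihood can be flat in an unused component, which
        # occasionally defeats the quasi-Newton line search; polish with a
        # simplex restart from the best point found.
        polish = optimize.minimize(
            objective, result.x, method="Nelder-Mead",
            options={"maxiter": 20000, "maxfev": 20000,
                     "xatol": 1e-6, "fatol": 1e-8},
        )
        if polish.fun <= result.fun:
            result = polish
    la1, lb1, la2, lb2, t = np.clip(result.x, _PARAM_BOUNDS[:, 0],
                                    _PARAM_BOUNDS[:, 1])
    prior = GPSPrior(
        alpha1=float(np.exp(la1)), beta1=float(np.exp(lb1)),
        alpha2=float(np.exp(la2)), beta2=float(np.exp(lb2)),
        mix_p=float(1.0 / (1.0 + np.exp(-t))),
        converged=bool(result.success),
        log_likelihood=float(-result.fun),
    )
    if not result.success:
        raise RuntimeError(
            f"gamma-mixture optimizer did not converge: {result.message} "
            f"(nit={result.nit}, fun={result.fun:.6g})")
    return prior


def _posterior_mixture(table: ContingencyTable, prior: GPSPrior):
    """Posterior over lambda: mixture of Gamma(alpha_j + a, beta_j + E) with
    weights proportional to prior weight x marginal evidence."""
    a, e = table.a, table.expected
    if e <= 0:
        raise ValueError("EBGM requires a positive expected count")
    log_w = np.array([
        (math.log(prior.mix_p) if prior.mix_p > 0 else -np.inf)
        + float(_nb_logpmf(np.array(a), prior.alpha1, prior.beta1, np.array(e))),
        (math.log1p(-prior.mix_p) if prior.mix_p < 1 else -np.inf)
        + float(_nb_logpmf(np.array(a), prior.alpha2, prior.beta2, np.array(e))),
    ])
    weights = np.exp(log_w - logsumexp(log_w))
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    return weights, shapes, rates


def ebgm(table: ContingencyTable, prior: GPSPrior) -> tuple[float, float]:
    """Shrunken observed/expected estimate: EBGM = exp(E[ln lambda | a]) and
    EBGM05, the posterior 5th percentile found by root-finding on the mixture
    gamma CDF."""
    weights, shapes, rates = _posterior_mixture(table, prior)
    mean_log = float(np.sum(weights * (digamma(shapes) - np.log(rates))))
    estimate = math.exp(mean_log)

    def cdf(lam: float) -> float:
        return float(np.sum(weights * stats.gamma.cdf(lam, shapes, scale=1.0 / rates)))

    # Bracket the 5th percentile; a near-zero shape parameter piles posterior
    # mass arbitrarily close to zero, so the lower bracket must adapt too.
    lo, hi = 1e-12, 1.0
    while cdf(hi) < 0.05:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - pathological prior
            break
    while cdf(lo) > 0.05:
        lo /= 1e6
        if lo < 1e-250:
            return (estimate, 0.0)
    q05 = optimize.brentq(lambda lam: cdf(lam) - 0.05, lo, hi, rtol=1e-6)
    return (estimate, float(q05))


def apply_signal_rule(row: SignalRow, thresholds: SignalThresholds | None = None) -> bool:
    """True iff all six conditions hold; NaN statistics never signal."""
    t = thresholds or SignalThresholds()
    return bool(
        row.table.a >= t.min_count
        and row.prr >= t.min_prr
        and row.chi2 >= t.min_chi2
        and row.ror_low > t.min_ror_low
        and row.ic025 > t.min_ic025
        and row.ebgm05 > t.min_ebgm05
    )


def compute_signals(
    tables: dict[str, ContingencyTable],
    level: str = "PT",
    prior: GPSPrior | None = None,
    thresholds: SignalThresholds | None = None,
    ror_continuity: bool = False,
    yates: bool = True,
    ic_method: str = "moment",
) -> list[SignalRow]:
    """All four estimators plus the combined flag for every event's table.

    The gamma-mixture prior is fitted across the supplied tables when not
    given (it is a property of the whole table collection, not of one pair).
    """
    if prior is None:
        prior = fit_gps_prior(tables)
    rows = []
    for event, table in sorted(tables.items()):
        row = SignalRow(event=event, level=level, table=table)
        row.ror, row.ror_low, row.ror_high = ror(table, continuity=ror_continuity)
        row.prr, row.chi2 = prr(table, yates=yates)
        row.ic, row.ic025 = bcpnn_ic(table, method=ic_method)
        if table.expected > 0:
            row.ebgm, row.ebgm05 = ebgm(table, prior)
        row.signal = apply_signal_rule(row, thresholds)
        rows.append(row)
    return rows


def rank_signals(rows: list[SignalRow], by: str = "ror", k: int | None = None) -> list[SignalRow]:
    """Top-k rows by descending ROR or co-report count; ties broken by event
    name ascending; NaN estimates sort last."""
    if by == "ror":
        def key(r: SignalRow):
            return (math.isnan(r.ror), -r.ror if not math.isnan(r.ror) else 0.0, r.event)
    elif by == "count":
        def key(r: SignalRow):
            return (-r.table.a, r.event)
    else:
        raise ValueError(f"rank key must be 'ror' or 'count', got {by!r}")
    ordered = sorted(rows, key=key)
    return ordered if k is None else ordered[:k]
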