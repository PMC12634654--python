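"""Time-to-onset (TTO) analysis of adverse-event reports.

TTO is the whole-day difference between the reported event date and the
therapy start date for the suspect drug. The hazard trend over time is
summarized by a two-parameter Weibull fit: shape beta < 1 indicates an
"early failure" profile (risk concentrated shortly after initiation and
decreasing), beta ~ 1 a constant hazard, beta > 1 a "wear-out" (increasing
hazard) profile. Spontaneous reports carry no at-risk denominator, so the
sample is treated as complete — no censoring model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ingest import SafetyReport

# Positive surrogate for same-day onsets in the Weibull likelihood only;
# raw zeros are retained for medians, IQRs and histograms.
ZERO_DAY_SURROGATE = 0.5


@dataclass
class TTOSample:
    """Onset times in days plus the exclusion audit trail."""

    values: np.ndarray
    n_excluded_missing: int = 0
    n_excluded_negative: int = 0

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class WeibullFit:
    shape: float
    scale: float
    shape_ci: tuple[float, float]
    scale_ci: tuple[float, float]
    failure_class: str
    median: float
    median_ci: tuple[float, float]
    log_likelihood: float
    n: int


def compute_tto(reports: list[SafetyReport]) -> TTOSample:
    """Event date minus therapy start in whole days; reports missing either
    date are excluded and counted, as are negative intervals. Zero is kept."""
    values = []
    n_missing = 0
    n_negative = 0
    for report in reports:
        if report.event_date is None or report.therapy_start is None:
            n_missing += 1
            continue
        days = (report.event_date - report.therapy_start).days
        if days < 0:
            n_negative += 1
            continue
        values.append(days)
    return TTOSample(values=np.asarray(values, dtype=float),
                     n_excluded_missing=n_missing, n_excluded_negative=n_negative)


def monthly_histogram(sample: TTOSample) -> list[tuple[int, int, float]]:
    """Counts per 30-day half-open month bin [30(m-1), 30m) with 2-dp
    percents of the sample size."""
    from .descriptives import percentage

    if sample.n == 0:
        raise ValueError("cannot histogram an empty sample")
    months = (sample.values // 30).astype(int) + 1
    out = []
    for m in range(1, int(months.max()) + 1):
        count = int((months == m).sum())
        out.append((m, count, percentage(count, sample.n)))
    return out


def _profile_equation(k: float, x: np.ndarray, log_x: np.ndarray,
                      mean_log: float) -> tuple[float, float]:
    xk = np.power(x, k)
    s0 = xk.sum()
    s1 = (xk * log_x).sum()
    s2 = (xk * log_x * log_x).sum()
    g = s1 / s0 - 1.0 / k - mean_log
    gprime = (s2 * s0 - s1 * s1) / (s0 * s0) + 1.0 / (k * k)
    return g, gprime


def _loglik(k: float, lam: float, x: np.ndarray, log_x: np.ndarray) -> float:
    n = len(x)
    return (n * math.log(k) - n * k * math.log(lam) + (k - 1) * log_x.sum()
            - float(np.power(x / lam, k).sum()))


def fit_weibull(sample: TTOSample | np.ndarray, max_iter: int = 200,
                tol: float = 1e-10) -> WeibullFit:
    """Maximum-likelihood Weibull fit via Newton iteration on the profile
    shape equation; 95% CIs are estimate +/- 1.96 SE from the inverse observed
    information, on the natural (not log) scale.

    Zero values are replaced by 0.5 day for the likelihood only.
    """
    x = sample.values if isinstance(sample, TTOSample) else np.asarray(sample, dtype=float)
    x = np.where(x == 0.0, ZERO_DAY_SURROGATE, x)
    if len(x) < 10:
        raise ValueError("need at least 10 positive onset times to fit")
    if np.any(x < 0):
        raise ValueError("onset times must be nonnegative")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate sample: all onset times equal")

    log_x = np.log(x)
    mean_log = float(log_x.mean())
    # Moment-style start: shape ~ 1.2 / sd(log x) is the usual initializer.
    sd_log = float(log_x.std())
    k = 1.2 / sd_log if sd_log > 0 else 1.0
    converged = False
    trace = []
    for _ in range(max_iter):
        g, gprime = _profile_equation(k, x, log_x, mean_log)
        step = g / gprime
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        trace.append((k, g))
        if abs(k_new - k) < tol * max(1.0, k):
            k = k_new
            converged = True
            break
        k = k_new
    if not converged:
        raise RuntimeError(f"Weibull shape iteration did not converge; trace tail "
                           f"{trace[-3:]}")
    lam = float((np.power(x, k).mean()) ** (1.0 / k))

    # Observed information by central finite differences of the log-likelihood.
    h_k, h_l = 1e-5 * max(k, 1e-3), 1e-5 * max(lam, 1e-3)

    def ll(kk: float, la: float) -> float:
        return _loglik(kk, la, x, log_x)

    d2k = (ll(k + h_k, lam) - 2 * ll(k, lam) + ll(k - h_k, lam)) / h_k**2
    d2l = (ll(k, lam + h_l) - 2 * ll(k, lam) + ll(k, lam - h_l)) / h_l**2
    dkl = (ll(k + h_k, lam + h_l) - ll(k + h_k, lam - h_l)
           - ll(k - h_k, lam + h_l) + ll(k - h_k, lam - h_l)) / (4 * h_k * h_l)
    info = -np.array([[d2k, dkl], [dkl, d2l]])
    cov = np.linalg.inv(info)
    se_k, se_l = math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))

    z = 1.959963984540054
    median = lam * math.log(2) ** (1.0 / k)
    # Delta method for the parametric median scale * (ln 2)^(1/k).
    dm_dk = median * (-math.log(math.log(2))) / k**2
    dm_dl = median / lam
    grad = np.array([dm_dk, dm_dl])
    se_m = math.sqrt(max(float(grad @ cov @ grad), 0.0))

    fit = WeibullFit(
        shape=k,
        scale=lam,
        shape_ci=(k - z * se_k, k + z * se_k),
        scale_ci=(lam - z * se_l, lam + z * se_l),
        failure_class="",
        median=median,
        median_ci=(median - z * se_m, median + z * se_m),
        log_likelihood=ll(k, lam),
        n=len(x),
    )
    fit.failure_class = classify_failure_type(fit)
    return fit


def classify_failure_type(fit: WeibullFit | float, band: float = 0.05) -> str:
    """Shape < 1 -> "early" (decreasing hazard), within +/- band of 1 ->
    "random", > 1 -> "wear-out"."""
    beta = fit.shape if isinstance(fit, WeibullFit) else float(fit)
    if abs(beta - 1.0) <= band:
        return "random"
    return "early" if beta < 1.0 else "wear-out"


def median_ci_normal(sample: TTOSample | np.ndarray) -> tuple[float, float, float]:
    """Sample median with a normal-approximation 95% CI,
    SE = 1 / (2 f(median) sqrt(n)) with f a Gaussian KDE.

    The lower bound is reported unclipped and can be negative even though
    onset times cannot be: that is a known artifact of the approximation
    near the boundary.
    """
    x = sample.values if isinstance(sample, TTOSample) else np.asarray(sample, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    med = float(np.median(x))
    kde = stats.gaussian_kde(x)
    f_med = float(kde(med)[0])
    if f_med <= 0:
        raise ValueError("density estimate at the median is zero")
    se = 1.0 / (2.0 * f_med * math.sqrt(len(x)))
    z = 1.959963984540054
    return (med, med - z * se, med + z * se)


def cumulative_incidence(sample: TTOSample | np.ndarray):
    """Empirical CDF as (day, cumulative percent) steps plus the median and
    IQR by linear-interpolation quantiles."""
    x = sample.values if isinstance(sample, TTOSample) else np.asarray(sample, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    days = np.sort(np.unique(x))
    n = len(x)
    xs = np.sort(x)
    cum = [(float(day), 100.0 * float(np.searchsorted(xs, day, side="right")) / n)
           for day in days]
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return {"curve": cum, "median": float(q50), "iqr": (float(q25), float(q75))}


def compare_strata(sample_a: TTOSample | np.ndarray, sample_b: TTOSample | np.ndarray) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of onset distributions (normal
    approximation with tie correction) plus medians and IQRs per stratum."""
    xa = sample_a.values if isinstance(sample_a, TTOSample) else np.asarray(sample_a, dtype=float)
    xb = sample_b.values if isinstance(sample_b, TTOSample) else np.asarray(sample_b, dtype=float)
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("each stratum needs at least 2 values")
    result = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
    qa = np.percentile(xa, [25, 50, 75])
    qb = np.percentile(xb, [25, 50, 75])
    return {
        "median_a": float(qa[1]), "iqr_a": (float(qa[0]), float(qa[2])),
        "median_b": float(qb[1]), "iqr_b": (float(qb[0]), float(qb[2])),
        "p_value": float(result.pvalue),
        "statistic": float(result.statistic),
    }
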