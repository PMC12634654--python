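"""2x2 construction and the four estimators against hand values and oracles."""

import datetime as dt
import math

import numpy as np
import pytest
from scipy import stats

import srsignal as s
from srsignal.disproportionality import (ContingencyTable, GPSPrior,
                                         SignalRow, _mixture_loglik,
                                         _nb_logpmf)


def _report(caseid, pts, drug="TARGET", role="PS"):
    return s.SafetyReport(primaryid=caseid, caseid=caseid,
                          fda_date=dt.date(2020, 1, 1), event_date=None,
                          event_year=None, sex="F", age_years=None,
                          country="US", reporter="MD",
                          drugs=[(drug, role)], reactions=list(pts))


class TestBuildTables:
    def test_toy_six_report_enumeration(self):
        cohort = [_report("1", ["X", "Y"]), _report("2", ["X"]), _report("3", ["Y"])]
        background = [_report("4", ["X"], drug="OTHER"),
                      _report("5", ["Y"], drug="OTHER"),
                      _report("6", ["Z"], drug="OTHER")]
        tables = s.build_tables(cohort, background)
        assert (tables["X"].a, tables["X"].b, tables["X"].c, tables["X"].d) == (2, 1, 1, 2)

    def test_background_only_event_has_zero_a(self):
        cohort = [_report("1", ["X"])]
        background = [_report("2", ["W"], drug="OTHER")] * 3
        tables = s.build_tables(cohort, background)
        assert (tables["W"].a, tables["W"].b) == (0, 1)

    def test_duplicate_pts_in_one_report_count_once(self):
        cohort = [_report("1", ["X", "X"])]
        background = [_report("2", ["X"], drug="OTHER")]
        assert s.build_tables(cohort, background)["X"].a == 1

    def test_all_tables_share_n_and_a_conserved(self, linked_cohort):
        cohort, background = linked_cohort
        tables = s.build_tables(cohort, background)
        n = len(cohort) + len(background)
        assert all(t.n == n for t in tables.values())
        mentions = sum(len(set(r.reactions)) for r in cohort)
        assert sum(t.a for t in tables.values()) == mentions

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="comparator"):
            s.build_tables([_report("1", ["X"])], [])


class TestROR:
    def test_independence_gives_one(self):
        t = ContingencyTable(10, 90, 20, 180)
        assert s.ror(t)[0] == pytest.approx(1.0)

    def test_formula_value(self):
        est, low, high = s.ror(ContingencyTable(5, 95, 100, 9800))
        assert est == pytest.approx(5.158, abs=5e-4)
        assert low > 1.0  # CI excludes 1
        assert low < est < high

    def test_zero_cell_policy(self):
        t = ContingencyTable(0, 100, 5, 95)
        assert math.isnan(s.ror(t)[0])
        est, low, high = s.ror(t, continuity=True)
        assert est > 0 and low < est < high


class TestPRR:
    def test_independence(self):
        est, chi2 = s.prr(ContingencyTable(10, 90, 20, 180))
        assert est == pytest.approx(1.0)
        assert chi2 < 0.1

    def test_formula_value(self):
        est, chi2 = s.prr(ContingencyTable(5, 95, 100, 9800))
        assert est == pytest.approx(4.950, abs=5e-4)
        assert chi2 > 4

    def test_zero_a_gives_zero_prr(self):
        est, _ = s.prr(ContingencyTable(0, 100, 5, 95))
        assert est == 0.0

    def test_yates_chi2_matches_scipy(self):
        t = ContingencyTable(12, 88, 40, 860)
        _, chi2 = s.prr(t)
        expected = stats.chi2_contingency(
            [[t.a, t.b], [t.c, t.d]], correction=True)[0]
        assert chi2 == pytest.approx(expected, rel=1e-10)


class TestBCPNN:
    def test_observed_equals_expected_gives_ic_near_zero(self):
        t = ContingencyTable(100, 900, 1000, 9000)  # a == E == 100
        ic, ic025 = s.bcpnn_ic(t)
        assert abs(ic) < 0.05
        assert ic025 < ic

    def test_zero_a_gives_negative_ic(self):
        ic, _ = s.bcpnn_ic(ContingencyTable(0, 1000, 1000, 9000))
        assert ic < 0

    def test_moment_estimate_matches_monte_carlo_posterior(self):
        """IC agrees with draws from the independent beta posteriors."""
        t = ContingencyTable(5, 95, 100, 9800)
        ic, ic025 = s.bcpnn_ic(t)
        rng = np.random.default_rng(12345)
        n, n1, n2, a = t.n, t.a + t.b, t.a + t.c, t.a
        g = (n + 2.0) * (n + 2.0) / ((n1 + 1.0) * (n2 + 1.0))
        draws = 100_000
        p11 = rng.beta(a + 1.0, g - 1.0 + n - a, size=draws)
        p1 = rng.beta(n1 + 1.0, 1.0 + n - n1, size=draws)
        p2 = rng.beta(n2 + 1.0, 1.0 + n - n2, size=draws)
        mc = np.log2(p11 / (p1 * p2))
        assert ic == pytest.approx(float(mc.mean()), abs=0.02)
        assert ic025 == pytest.approx(float(mc.mean() - 2 * mc.std()), abs=0.05)

    def test_shrinkage_variant(self):
        t = ContingencyTable(5, 95, 100, 9800)
        ic, ic025 = s.bcpnn_ic(t, method="shrinkage")
        assert ic == pytest.approx(math.log2(5.5 / (t.expected + 0.5)), abs=1e-9)
        assert ic025 < ic


def _tables_from_counts(a_values, e=5.0, n_cohort=100, n_total=10_000):
    tables = []
    for a in a_values:
        b = n_cohort - a
        c = int(round(e * n_total / n_cohort)) - a
        tables.append(ContingencyTable(a, b, max(c, 0), n_total - a - b - max(c, 0)))
    return tables


class TestGPSPrior:
    def test_single_gamma_truth_recovered_in_likelihood(self):
        """Fitted marginal likelihood is at least that of the generating
        prior (minus 1 nat of optimizer slack)."""
        rng = np.random.default_rng(0)
        alpha, beta = 2.0, 2.0
        # Margins chosen so that E = (a+b)(a+c)/N equals the intended
        # expected count: a+b = 1000, N = 10^6, a+c = round(1000 * e).
        tables = []
        for _ in range(300):
            e_target = rng.uniform(0.5, 20.0)
            lam = rng.gamma(alpha, 1.0 / beta)
            a = int(rng.poisson(lam * e_target))
            margin = int(round(1000 * e_target))
            a = min(a, margin, 1000)
            tables.append(ContingencyTable(
                a, 1000 - a, margin - a, 1_000_000 - 1000 - margin + a))
        prior = s.fit_gps_prior(tables)
        av = np.array([t.a for t in tables], dtype=float)
        ev = np.array([t.expected for t in tables])
        truth_ll = float(np.sum(_nb_logpmf(av, alpha, beta, ev)))
        assert prior.log_likelihood >= truth_ll - 1.0

    def test_fitted_parameters_satisfy_constraints(self, linked_cohort):
        cohort, background = linked_cohort
        prior = s.fit_gps_prior(s.build_tables(cohort, background))
        assert min(prior.alpha1, prior.beta1, prior.alpha2, prior.beta2) > 0
        assert 0.0 <= prior.mix_p <= 1.0
        assert prior.converged

    def test_order_invariance(self, linked_cohort):
        cohort, background = linked_cohort
        tables = list(s.build_tables(cohort, background).values())
        p1 = s.fit_gps_prior(tables)
        p2 = s.fit_gps_prior(list(reversed(tables)))
        assert (p1.alpha1, p1.beta1, p1.alpha2, p1.beta2, p1.mix_p) == \
               (p2.alpha1, p2.beta1, p2.alpha2, p2.beta2, p2.mix_p)

    def test_too_few_tables_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            s.fit_gps_prior(_tables_from_counts([1] * 5))


class TestEBGM:
    def test_single_component_conjugate_closed_form(self):
        prior = GPSPrior(alpha1=2.0, beta1=2.0, alpha2=1.0, beta2=1.0, mix_p=1.0)
        t = ContingencyTable(8, 92, 100, 9800)
        estimate, q05 = s.ebgm(t, prior)
        e = t.expected
        post = stats.gamma(a=2.0 + 8, scale=1.0 / (2.0 + e))
        from scipy.special import digamma
        assert estimate == pytest.approx(math.exp(digamma(10) - math.log(2 + e)), rel=1e-9)
        assert q05 == pytest.approx(post.ppf(0.05), rel=1e-5)

    def test_data_dominate_at_large_counts(self):
        prior = GPSPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, mix_p=1 / 3)
        t = ContingencyTable(2000, 8000, 20_000, 80_000)  # a/E = 1
        estimate, _ = s.ebgm(t, prior)
        assert estimate == pytest.approx(1.0, abs=0.05)

    def test_small_count_shrinks_toward_one(self):
        prior = GPSPrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, mix_p=1 / 3)
        t = ContingencyTable(5, 95, 5, 9895)  # a/E ~ 10
        estimate, q05 = s.ebgm(t, prior)
        assert estimate < t.a / t.expected
        assert q05 < estimate


class TestSignalRuleAndRanking:
    def _row(self, a=10, prr=3.0, chi2=12.0, ror_low=1.4, ic025=0.3, ebgm05=2.5):
        row = SignalRow(event="X", level="PT",
                        table=ContingencyTable(a, 100 - a, 50, 950))
        row.prr, row.chi2, row.ror_low, row.ic025, row.ebgm05 = (
            prr, chi2, ror_low, ic025, ebgm05)
        return row

    def test_all_thresholds_met(self):
        assert s.apply_signal_rule(self._row()) is True

    @pytest.mark.parametrize("kwargs", [
        {"prr": 1.9}, {"chi2": 3.9}, {"ror_low": 1.0}, {"ic025": 0.0},
        {"ebgm05": 2.0}, {"a": 2},
    ])
    def test_single_threshold_failure(self, kwargs):
        assert s.apply_signal_rule(self._row(**kwargs)) is False

    def test_nan_statistics_never_signal(self):
        assert s.apply_signal_rule(self._row(prr=math.nan)) is False

    def test_rank_by_ror_with_ties_alphabetical(self):
        rows = [self._row(), self._row(), self._row()]
        rows[0].event, rows[0].ror = "B", 2.0
        rows[1].event, rows[1].ror = "A", 2.0
        rows[2].event, rows[2].ror = "C", 5.0
        ranked = s.rank_signals(rows, by="ror")
        assert [r.event for r in ranked] == ["C", "A", "B"]

    def test_rank_by_count_and_oversized_k(self):
        rows = [self._row(a=3), self._row(a=9), self._row(a=6)]
        for row, name in zip(rows, ["x", "y", "z"]):
            row.event = name
        ranked = s.rank_signals(rows, by="count", k=10)
        assert [r.table.a for r in ranked] == [9, 6, 3]
        assert len(s.rank_signals(rows, by="count", k=2)) == 2
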