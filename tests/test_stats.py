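"""Disproportionality statistics: point estimates, intervals, prior fit,
shrinkage, criteria and ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats as sps

from pvsignal.cohort import ContingencyTable
from pvsignal.stats import (
    GPSPrior,
    SignalScores,
    bcpnn_ic,
    ebgm_stat,
    evaluate_signal,
    fit_gps_prior,
    prr_stat,
    rank_signals,
    ror_stat,
    score_table,
    signal_flags,
    solve_background_count,
)


class TestROR:
    def test_cross_product_by_hand(self):
        ror, lo, hi = ror_stat(ContingencyTable(10, 90, 100, 9900))
        assert ror == pytest.approx(11.0)
        assert lo < 11.0 < hi

    def test_independence_gives_one(self):
        ror, _, _ = ror_stat(ContingencyTable(10, 90, 100, 900))
        assert ror == pytest.approx(1.0)

    def test_zero_cell_continuity(self):
        ror, lo, hi = ror_stat(ContingencyTable(5, 0, 10, 100))
        assert np.isfinite([ror, lo, hi]).all() and ror > 0

    def test_a_zero_is_defined_but_null(self):
        assert ror_stat(ContingencyTable(0, 10, 10, 100)) == (0.0, 0.0, 0.0)


class TestPRR:
    def test_hand_computation(self):
        prr, _ = prr_stat(ContingencyTable(10, 90, 100, 9900))
        assert prr == pytest.approx(10.0)

    def test_independence(self):
        prr, chi2 = prr_stat(ContingencyTable(10, 90, 100, 900))
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_prr_ror_identity_on_random_tables(self):
        """prr = ror * (b/(a+b)) * ((c+d)/d), an algebraic identity."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 2000, size=4)
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            ror = ror_stat(t)[0]
            prr = prr_stat(t)[0]
            assert prr == pytest.approx(ror * (b / (a + b)) * ((c + d) / d), rel=1e-10)

    def test_chi2_matches_scipy_pearson(self):
        """Cross-check the chi-square against the independent implementation."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = (int(v) for v in rng.integers(5, 500, size=4))
            _, chi2 = prr_stat(ContingencyTable(a, b, c, d))
            expected = sps.chi2_contingency([[a, b], [c, d]], correction=False)[0]
            assert chi2 == pytest.approx(expected, rel=1e-10)


class TestBCPNN:
    def test_independence_limit(self):
        """A large balanced independent table has IC near zero."""
        ic, _, _ = bcpnn_ic(ContingencyTable(10_000, 90_000, 100_000, 900_000))
        assert abs(ic) < 0.01

    def test_degenerate_table_is_finite(self):
        ic, lo, hi = bcpnn_ic(ContingencyTable(1, 0, 0, 0))
        assert np.isfinite([ic, lo, hi]).all()

    def test_interval_brackets_point(self):
        ic, lo, hi = bcpnn_ic(ContingencyTable(50, 450, 500, 9000))
        assert lo <= ic <= hi

    def test_large_n_converges_to_log2_relative_rate(self):
        """As N grows at fixed ratios, IC -> log2 of the observed/expected rate."""
        for scale in (1_000, 1_000_000):
            a, b, c, d = 4 * scale, 96 * scale, 100 * scale, 9800 * scale
            t = ContingencyTable(a, b, c, d)
            rr = a * t.n / ((a + b) * (a + c))
            ic, _, _ = bcpnn_ic(t)
            if scale == 1_000_000:
                assert ic == pytest.approx(math.log2(rr), abs=1e-3)


class TestGPSPriorFit:
    def test_null_simulation_recovers_unit_mean(self):
        """n ~ Poisson(E) with lambda = 1 everywhere: prior mean near 1."""
        rng = np.random.default_rng(42)
        e = rng.uniform(20, 200, size=400)
        n = rng.poisson(e)
        prior = fit_gps_prior(list(zip(n, e)))
        assert 0.9 <= prior.mean <= 1.1

    def test_two_group_simulation_recovers_mixture(self):
        """90% null, 10% lambda=5: one component sits at elevated mean with
        roughly the right weight."""
        rng = np.random.default_rng(43)
        e = rng.uniform(20, 100, size=500)
        lam = np.where(rng.random(500) < 0.1, 5.0, 1.0)
        n = rng.poisson(lam * e)
        prior = fit_gps_prior(list(zip(n, e)))
        means = [(prior.w, prior.alpha1 / prior.beta1), (1 - prior.w, prior.alpha2 / prior.beta2)]
        weight, mean = max(means, key=lambda wm: wm[1])
        assert 3.0 <= mean <= 8.0
        assert 0.05 <= weight <= 0.2

    def test_scale_invariance_of_argmax(self):
        """Duplicating every pair 100x rescales the likelihood, not its argmax."""
        pairs = [(3, 2.0), (10, 9.5), (1, 4.0), (7, 2.5)]
        p1 = fit_gps_prior(pairs)
        p100 = fit_gps_prior(pairs * 100)
        assert p100.mean == pytest.approx(p1.mean, rel=1e-3)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fit_gps_prior([(1, 1.0)])
        with pytest.raises(ValueError):
            fit_gps_prior([(1, 0.0), (2, 1.0)])


class TestEBGM:
    def test_digamma_closed_form(self):
        """Degenerate prior w=1, Gamma(2,2); n=8, E=2 -> posterior Gamma(10,4)."""
        prior = GPSPrior(2.0, 2.0, 1.0, 1.0, 1.0)
        ebgm, ebgm05 = ebgm_stat(8, 2.0, prior)
        assert ebgm == pytest.approx(math.exp(special.digamma(10) - math.log(4)), rel=1e-10)
        # 5th percentile of Gamma(10, rate 4), independent quantile oracle
        assert ebgm05 == pytest.approx(sps.gamma.ppf(0.05, 10, scale=0.25), abs=1e-7)

    def test_shrinkage_vanishes_at_unit_rate(self):
        prior = GPSPrior(1.0, 1.0, 2.0, 2.0, 0.5)
        ebgm, _ = ebgm_stat(10_000, 10_000.0, prior)
        assert 0.99 <= ebgm <= 1.01

    def test_large_n_approaches_n_over_e(self):
        prior = GPSPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)
        ebgm, _ = ebgm_stat(50_000, 10_000.0, prior)
        assert ebgm == pytest.approx(5.0, rel=0.01)

    def test_ebgm05_below_ebgm(self):
        prior = GPSPrior(0.5, 0.3, 2.0, 2.0, 0.4)
        for n, e in [(3, 1.0), (20, 4.0), (100, 100.0)]:
            ebgm, ebgm05 = ebgm_stat(n, e, prior)
            assert ebgm05 <= ebgm


class TestCriteria:
    def _scores(self, **kw):
        base = dict(
            case_count=10, ror=3, ror_lo=2, ror_hi=4, prr=3, chi2=10,
            ic=1, ic_lo=0.5, ic_hi=1.5, ebgm=3, ebgm05=2.5,
        )
        base.update(kw)
        return SignalScores(**base)

    def test_all_flags_true_is_pt_signal(self):
        s = self._scores()
        assert all(signal_flags(s).values())
        assert evaluate_signal(s, "PT") and evaluate_signal(s, "SOC")

    def test_single_flag_is_soc_but_not_pt_signal(self):
        s = self._scores(ror_lo=0.5, prr=1.0, ebgm05=1.0)  # only BCPNN fires
        flags = signal_flags(s)
        assert sum(flags.values()) == 1
        assert not evaluate_signal(s, "PT")
        assert evaluate_signal(s, "SOC")

    def test_minimum_count_guard(self):
        s = self._scores(case_count=2, ror=1e6, ror_lo=1e5)
        assert not signal_flags(s)["ror"]
        assert not signal_flags(s)["prr"]


class TestMonotonicity:
    def test_all_point_estimates_nondecreasing_in_a(self):
        """At fixed b, c, d all four estimates grow with a."""
        prior = GPSPrior(0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)
        prev = None
        for a in (1, 5, 20, 80, 300):
            t = ContingencyTable(a, 500, 1000, 100_000)
            vals = (
                ror_stat(t)[0],
                prr_stat(t)[0],
                bcpnn_ic(t)[0],
                ebgm_stat(t.a, t.expected, prior)[0],
            )
            if prev is not None:
                assert all(v >= p for v, p in zip(vals, prev))
            prev = vals


class TestRanking:
    def _table(self):
        return pd.DataFrame(
            {
                "a": [5, 3, 5],
                "ror_lo": [1.5, 9.0, 2.0],
            },
            index=pd.Index(["PT_B", "PT_C", "PT_A"], name="term"),
        )

    def test_frequency_order(self):
        out = rank_signals(self._table(), "frequency", 3)
        assert list(out.index) == ["PT_A", "PT_B", "PT_C"]

    def test_intensity_order(self):
        out = rank_signals(self._table(), "intensity", 2)
        assert list(out.index) == ["PT_C", "PT_A"]

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            rank_signals(self._table(), "frequency", 0)

    def test_injected_pt_ranks_first_by_intensity(self, small_analysis):
        top = rank_signals(small_analysis.scores, "intensity", 5)
        assert "PT_100" in set(top.index[:3])


class TestSolveBackgroundCount:
    def test_inverts_ror_example(self):
        assert solve_background_count(10, 90, 11.0, 10_000) == pytest.approx(100.0)

    def test_symmetry_at_ror_one(self):
        assert solve_background_count(50, 50, 1.0, 10_000) == pytest.approx(5000.0)

    def test_round_trip_identity(self):
        a, b, ror, rest = 2756, 80101, 3.35, 52_290_349
        c = solve_background_count(a, b, ror, rest)
        got = (a * (rest - c)) / (b * c)
        assert got == pytest.approx(ror, rel=1e-12)

    def test_infeasible(self):
        with pytest.raises(ValueError):
            solve_background_count(10, 90, -1.0, 100)


def test_score_table_flags_injected_signals(small_analysis):
    scores = small_analysis.scores
    assert scores.loc["PT_100", "signal_pt"]
    assert scores.loc["PT_150", "signal_pt"]
    # deterministic row order
    assert list(scores.index) == sorted(scores.index)
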