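"""Survival correlation, exponential fits, bootstrap, leaflet averaging."""

import warnings

import numpy as np
import pytest

from lipidsite import (DegenerateFitError, EstimationError, ParameterError,
                       SurvivalCurve, bootstrap_residence_time,
                       fit_double_exponential, fit_single_exponential,
                       leaflet_average, select_fit, survival_correlation)
from lipidsite.synthetic import simulate_interval_ensemble
from oracles import sigma_oracle


def _ideal_curve(lags, sigma, T, dt):
    big = np.full(lags.size, 1e6)
    return SurvivalCurve(lags, sigma, big, np.ones(lags.size, int), 10, T,
                         dt, contributors=np.full(lags.size, 1e3))


class TestSurvivalCorrelation:
    def test_fully_bound_lipid_gives_flat_one(self):
        curve = survival_correlation([[(0.0, 10.0)]], T=10.0, dt_lag=1.0)
        assert np.allclose(curve.sigma, 1.0)

    def test_sigma_zero_is_one_for_any_input(self):
        curve = survival_correlation([[(0.5, 3.7)], [(2.0, 9.0)]], T=10.0)
        assert curve.sigma[0] == pytest.approx(1.0)

    def test_single_interval_matches_window_oracle(self):
        sets = [[(0.0, 4.0)]]
        curve = survival_correlation(sets, T=10.0, dt_lag=1.0)
        lags, sig = sigma_oracle(sets, T=10.0, dt=1.0)
        np.testing.assert_allclose(curve.lags, lags)
        np.testing.assert_allclose(curve.sigma, sig, atol=1e-12)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_window_oracle_on_random_ensembles(self, seed):
        rng = np.random.default_rng(seed)
        T = float(rng.integers(8, 40))
        sets = []
        for _ in range(rng.integers(1, 5)):
            ivs, cursor = [], 0.0
            while True:
                a = cursor + rng.uniform(0.2, 4.0)
                b = a + rng.uniform(0.3, 6.0)
                if a >= T:
                    break
                ivs.append((a, min(b, T + 2.0)))
                cursor = b
            sets.append(ivs)
        if not any(s for s in sets):
            sets[0] = [(0.0, T / 2)]
        curve = survival_correlation(sets, T=T, dt_lag=1.0)
        lags, sig = sigma_oracle(sets, T=T, dt=1.0)
        np.testing.assert_allclose(curve.sigma, sig, atol=1e-12)

    def test_no_interacting_lipids_raises(self):
        with pytest.raises(EstimationError):
            survival_correlation([[], []], T=10.0)

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(42)
        sets = [[(float(a), float(a) + float(d))]
                for a, d in zip(rng.uniform(0, 50, 20), rng.uniform(1, 30, 20))]
        curve = survival_correlation(sets, T=100.0, dt_lag=1.0)
        assert np.all(np.diff(curve.sigma) <= 1e-12)

    def test_adding_an_interval_only_increases_raw_counts(self):
        base = [[(5.0, 20.0)], [(30.0, 40.0)]]
        more = [base[0] + [(60.0, 70.0)], base[1]]
        c0 = survival_correlation(base, T=100.0)
        c1 = survival_correlation(more, T=100.0)
        assert np.all(c1.counts >= c0.counts)


class TestSingleExponentialFit:
    def test_exact_model_recovery(self):
        t = np.arange(0.0, 1001.0, 1.0)
        fit = fit_single_exponential(_ideal_curve(t, np.exp(-t / 100.0),
                                                  1001.0, 1.0))
        assert fit.theta == pytest.approx(100.0, rel=1e-6)

    def test_flat_curve_is_degenerate(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(DegenerateFitError):
            fit_single_exponential(_ideal_curve(t, np.ones_like(t), 100.0, 1.0))

    def test_recovery_from_exponential_dwells(self):
        sets, T = simulate_interval_ensemble(80, 5, 200.0, seed=9)
        curve = survival_correlation(sets, T, dt_lag=4.0)
        fit = fit_single_exponential(curve)
        assert fit.theta == pytest.approx(200.0, rel=0.15)


class TestDoubleExponentialFit:
    def test_exact_model_recovery_within_one_percent(self):
        t = np.arange(0.0, 20000.0, 5.0)
        y = 0.5 * np.exp(-t / 100.0) + 0.5 * np.exp(-t / 5000.0)
        fit = fit_double_exponential(_ideal_curve(t, y, 20000.0, 5.0))
        assert fit.model == "double"
        assert fit.theta1 == pytest.approx(100.0, rel=0.01)
        assert fit.theta2 == pytest.approx(5000.0, rel=0.01)
        assert fit.A == pytest.approx(0.5, rel=0.01)
        assert fit.B == pytest.approx(0.5, rel=0.01)
        assert fit.theta == fit.theta2  # long population reported

    def test_pure_single_input_collapses_to_single(self):
        t = np.arange(0.0, 20000.0, 5.0)
        with pytest.warns(UserWarning, match="collapse"):
            fit = fit_double_exponential(
                _ideal_curve(t, np.exp(-t / 800.0), 20000.0, 5.0))
        assert fit.model == "single"
        assert fit.theta == pytest.approx(800.0, rel=0.01)

    def test_mixture_recovery_median_within_25_percent(self):
        # 70/30 mixture of 100 ns and 5 us dwells, 1000 events per replicate
        th1s, th2s = [], []
        for rep in range(5):
            sets, T = simulate_interval_ensemble(
                100, 10, [100.0, 5000.0], weights=[0.7, 0.3], seed=40 + rep)
            curve = survival_correlation(sets, T, dt_lag=5.0)
            fit = fit_double_exponential(curve)
            assert fit.model == "double"
            th1s.append(fit.theta1)
            th2s.append(fit.theta2)
        assert np.median(th1s) == pytest.approx(100.0, rel=0.25)
        assert np.median(th2s) == pytest.approx(5000.0, rel=0.25)

    def test_selected_double_never_has_worse_rss_than_single(self):
        # nested-model consistency: whenever auto selection reports two
        # populations, the two-population fit must beat the single fit
        for seed in (5, 6, 7):
            sets, T = simulate_interval_ensemble(
                60, 8, [100.0, 2000.0], weights=[0.6, 0.4], seed=seed)
            curve = survival_correlation(sets, T, dt_lag=4.0)
            single = fit_single_exponential(curve)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = select_fit(curve, model="auto")
            if fit.model == "double":
                assert fit.rss < single.rss


class TestModelSelection:
    def test_auto_prefers_double_on_two_population_data(self):
        sets, T = simulate_interval_ensemble(
            100, 10, [100.0, 5000.0], weights=[0.7, 0.3], seed=21)
        curve = survival_correlation(sets, T, dt_lag=5.0)
        assert select_fit(curve, model="auto").model == "double"

    def test_auto_keeps_single_on_one_population_data(self):
        sets, T = simulate_interval_ensemble(100, 6, 500.0, seed=22)
        curve = survival_correlation(sets, T, dt_lag=5.0)
        fit = select_fit(curve, model="auto")
        assert fit.theta == pytest.approx(500.0, rel=0.2)

    def test_unknown_model_rejected(self):
        t = np.arange(0.0, 100.0, 1.0)
        with pytest.raises(ParameterError):
            select_fit(_ideal_curve(t, np.exp(-t / 10), 100.0, 1.0),
                       model="triple")


class TestBootstrap:
    def test_identical_lipids_have_zero_sd(self):
        sets = [[(10.0, 400.0), (700.0, 950.0)]] * 8
        boot = bootstrap_residence_time(sets, T=1000.0, n_boot=100, seed=0,
                                        dt_lag=5.0)
        assert boot.sd == 0.0

    def test_fixed_seed_is_bit_reproducible(self):
        sets, T = simulate_interval_ensemble(20, 4, 100.0, seed=3)
        b1 = bootstrap_residence_time(sets, T, n_boot=60, seed=17, dt_lag=5.0)
        b2 = bootstrap_residence_time(sets, T, n_boot=60, seed=17, dt_lag=5.0)
        assert b1.sd == b2.sd
        assert np.array_equal(b1.samples, b2.samples)

    def test_requires_two_lipids(self):
        with pytest.raises(EstimationError):
            bootstrap_residence_time([[(0.0, 5.0)]], T=10.0, n_boot=10)

    def test_sd_tracks_replication_sd_within_factor_two(self):
        # bootstrap SD vs the SD of estimates over independent regenerations
        thetas = []
        for rep in range(30):
            sets, T = simulate_interval_ensemble(40, 5, 200.0, seed=600 + rep)
            curve = survival_correlation(sets, T, dt_lag=5.0)
            thetas.append(fit_single_exponential(curve).theta)
        replication_sd = np.std(thetas, ddof=1)
        sets, T = simulate_interval_ensemble(40, 5, 200.0, seed=600)
        boot = bootstrap_residence_time(sets, T, n_boot=200, seed=1,
                                        dt_lag=5.0)
        assert replication_sd / 2 <= boot.sd <= replication_sd * 2


class TestLeafletAverage:
    def test_arithmetic_mean(self):
        assert leaflet_average(200.0, 100.0) == pytest.approx(150.0)

    def test_identity(self):
        assert leaflet_average(321.0, 321.0) == pytest.approx(321.0)

    def test_missing_propagates_nan_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            assert np.isnan(leaflet_average(None, 100.0))

    def test_symmetric_system_average_consistent(self):
        si, T1 = simulate_interval_ensemble(50, 5, 300.0, seed=31)
        so, T2 = simulate_interval_ensemble(50, 5, 300.0, seed=32)
        ti = fit_single_exponential(
            survival_correlation(si, T1, dt_lag=6.0)).theta
        to = fit_single_exponential(
            survival_correlation(so, T2, dt_lag=6.0)).theta
        avg = leaflet_average(ti, to)
        assert min(ti, to) <= avg <= max(ti, to)
        assert avg == pytest.approx(300.0, rel=0.2)
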