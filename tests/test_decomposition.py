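"""Additive model fitting: trend, periodogram, Fisher G, harmonics, AR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bactoseries import (
    MonthlySeries,
    SeriesSpec,
    decompose,
    fisher_g_test,
    fit_ar,
    fit_harmonics,
    fit_trend,
    generate_series,
    periodogram,
    t_max,
)
from bactoseries.decomposition import _pairwise_acf, _pacf_from_acf


class TestFitTrend:
    def test_perfect_line_recovered(self):
        t = np.arange(48)
        s = MonthlySeries(2.0 * t + 1.0)
        trend = fit_trend(s)
        assert trend.slope_per_month == pytest.approx(2.0)
        assert trend.intercept == pytest.approx(1.0)
        assert trend.pct_variance == pytest.approx(100.0)
        assert trend.slope_per_year == pytest.approx(24.0)

    def test_constant_series_not_retained(self):
        assert fit_trend(MonthlySeries(np.full(48, 3.0))) is None

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_trend(MonthlySeries(np.arange(10.0)))

    def test_known_slope_recovered_across_seeds(self):
        # LNA-abundance-scale decadal trend: b = 0.016/yr in log10 units
        hits = 0
        n_sims = 200
        for seed in range(n_sims):
            spec = SeriesSpec(
                n_months=120, mean=5.47, trend_slope_b=0.016 / 12,
                noise_sd=0.225, seed=seed,
            )
            s = generate_series(spec)
            res = np.polyfit(s.t, s.values, 1, cov=True)
            (b, _), cov = res
            se = math.sqrt(cov[0, 0])
            hits += abs(b - 0.016 / 12) <= 2 * se
        assert hits / n_sims >= 0.93


class TestPeriodogram:
    def test_pure_fourier_cosine_gives_single_ordinate(self):
        t = np.arange(120)
        x = np.cos(2 * np.pi * t / 12.0)
        freqs, I = periodogram(x)
        peak = np.argmax(I)
        assert freqs[peak] == pytest.approx(1 / 12)
        others = np.delete(I, peak)
        assert others.max() < 1e-20 * I[peak]

    def test_parseval_identity(self, white_noise_series):
        x = white_noise_series.values
        _, I = periodogram(x)
        n = x.size
        # even n: variance = (2/n) sum I_j + Nyquist term
        X = np.fft.rfft(x - x.mean())
        nyquist = np.abs(X[-1]) ** 2 / n
        assert (2 * I.sum() + nyquist) / n == pytest.approx(np.var(x), rel=1e-10)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            periodogram(np.ones(5))

    def test_gapped_series_uses_observed_months_only(self):
        t = np.arange(120.0)
        x = np.cos(2 * np.pi * t / 12.0)
        x[::7] = np.nan
        freqs, I = periodogram(x)
        assert freqs[np.argmax(I)] == pytest.approx(1 / 12)


class TestFisherG:
    def test_all_variance_at_one_frequency_is_certain(self):
        I = np.zeros(30)
        I[4] = 1.0
        g, p = fisher_g_test(I)
        assert g == 1.0
        assert p < 1e-12

    def test_p_value_matches_monte_carlo_null(self):
        # iid exponential ordinates: compare the closed form with simulation
        m = 25
        rng = np.random.default_rng(1)
        sims = rng.exponential(size=(4000, m))
        gs = sims.max(axis=1) / sims.sum(axis=1)
        for g0 in (0.15, 0.2, 0.3):
            from bactoseries.decomposition import _fisher_g_pvalue

            exact = _fisher_g_pvalue(g0, m)
            empirical = (gs > g0).mean()
            assert empirical == pytest.approx(exact, abs=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fisher_g_test(np.zeros(20))


class TestFitHarmonics:
    def test_noiseless_annual_cycle_exact(self, annual_cosine_series):
        fit = decompose(annual_cosine_series)
        assert len(fit.harmonics) == 1
        h = fit.harmonics[0]
        assert h.period == 12.0
        assert h.amplitude == pytest.approx(0.04, abs=1e-12)
        assert h.phase == pytest.approx(2.44, abs=1e-12)
        assert fit.climatological_mean == pytest.approx(-1.29, abs=1e-12)

    def test_two_tone_recovered_in_amplitude_order(self):
        spec = SeriesSpec(
            n_months=120, harmonics=((12.0, 2.0, 1.0), (6.0, 1.0, 2.5)), noise_sd=0.0
        )
        s = generate_series(spec)
        comps = fit_harmonics(s)
        assert len(comps) == 2
        assert comps[0].period == pytest.approx(12.0)
        assert comps[1].period == pytest.approx(6.0)
        assert comps[0].amplitude == pytest.approx(2.0, abs=1e-9)
        assert comps[1].amplitude == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_mostly_yields_no_components(self):
        empty = 0
        n_sims = 100
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            s = MonthlySeries(rng.normal(size=120))
            empty += not fit_harmonics(s)
        assert empty / n_sims >= 0.85

    def test_gapped_annual_cycle_recovered(self):
        spec = SeriesSpec(
            n_months=120, harmonics=((12.0, 3.89, 4.26),), noise_sd=1.0,
            missing_fraction=0.05, seed=2,
        )
        comps = fit_harmonics(generate_series(spec))
        assert comps
        assert comps[0].period == pytest.approx(12.0, abs=0.5)
        assert comps[0].amplitude == pytest.approx(3.89, rel=0.15)


class TestTmax:
    @pytest.mark.parametrize(
        "theta,T,expected",
        [(4.26, 12.0, 8.136), (0.0, 12.0, 0.0), (math.pi, 12.0, 6.0)],
    )
    def test_phase_to_month_of_maximum(self, theta, T, expected):
        assert t_max(theta, T) == pytest.approx(expected, abs=5e-3)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(theta=st.floats(0, 2 * math.pi, exclude_max=True), T=st.floats(2, 60))
    def test_t_max_lies_within_one_period(self, theta, T):
        assert 0 <= t_max(theta, T) < T

    def test_phase_convention_self_consistency(self):
        # fitted component's empirical argmax equals t_max mod T
        spec = SeriesSpec(n_months=120, harmonics=((12.0, 1.0, 4.26),), noise_sd=0.0)
        fit = decompose(generate_series(spec))
        h = fit.harmonics[0]
        t_fine = np.arange(0, 12, 0.01)
        argmax = t_fine[np.argmax(h.predict(t_fine))]
        assert argmax == pytest.approx(h.t_max % h.period, abs=0.01)


class TestFitAr:
    def test_ar1_coefficient_recovered(self):
        # temperature-row persistence: phi = 0.34 at lag 1
        spec = SeriesSpec(n_months=120, ar_coefficient_phi=0.34, noise_sd=1.0, seed=8)
        s = generate_series(spec)
        comp = fit_ar(s.values - s.values.mean())
        assert comp is not None
        se = math.sqrt((1 - 0.34**2) / 120)
        assert comp.phi == pytest.approx(0.34, abs=2.5 * se)

    def test_white_noise_mostly_absent(self):
        absent = 0
        n_sims = 200
        for seed in range(n_sims):
            rng = np.random.default_rng(seed)
            absent += fit_ar(rng.normal(size=120)) is None
        assert absent / n_sims >= 0.9

    def test_strong_persistence_always_found_at_lag_one(self):
        found = 0
        n_sims = 50
        for seed in range(n_sims):
            spec = SeriesSpec(
                n_months=120, ar_coefficient_phi=0.9, noise_sd=1.0, seed=seed
            )
            comp = fit_ar(generate_series(spec).values)
            found += comp is not None and comp.lag == 1
        assert found / n_sims >= 0.98

    def test_pacf_matches_statsmodels_on_gapfree_data(self):
        statsmodels = pytest.importorskip("statsmodels.tsa.stattools")
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        for t in range(2, 300):
            x[t] += 0.5 * x[t - 1]
        ours = _pacf_from_acf(_pairwise_acf(x, 5))
        theirs = statsmodels.pacf(x, nlags=5, method="ywm")
        np.testing.assert_allclose(ours[1:], theirs[1:], atol=0.05)


class TestDecompose:
    def test_ledger_total_is_sum_of_parts(self):
        spec = SeriesSpec(
            n_months=120, mean=15.7, trend_slope_b=0.002,
            harmonics=((12.0, 3.89, 4.26),), ar_coefficient_phi=0.34,
            noise_sd=1.276, seed=4,
        )
        fit = decompose(generate_series(spec))
        ledger = fit.variance_ledger()
        parts = sum(v for k, v in ledger.items() if k != "total")
        assert ledger["total"] == pytest.approx(parts, abs=1e-12)
        assert ledger["total"] <= 100.0 + 1e-6

    def test_residual_mean_near_zero(self):
        spec = SeriesSpec(
            n_months=120, mean=5.0, harmonics=((12.0, 1.0, 1.0),),
            ar_coefficient_phi=0.3, noise_sd=0.5, seed=6,
        )
        fit = decompose(generate_series(spec))
        resid = fit.residuals[np.isfinite(fit.residuals)]
        assert abs(resid.mean()) < 3 * resid.std() / math.sqrt(resid.size)

    def test_idempotent_on_own_residuals(self):
        # re-decomposing the residuals finds nothing in most seeds
        clean = 0
        n_sims = 40
        for seed in range(n_sims):
            spec = SeriesSpec(
                n_months=120, harmonics=((12.0, 2.0, 1.0),),
                ar_coefficient_phi=0.3, noise_sd=1.0, seed=seed,
            )
            fit = decompose(generate_series(spec))
            refit = decompose(MonthlySeries(fit.residuals))
            clean += (
                refit.trend is None and not refit.harmonics and refit.ar is None
            )
        assert clean / n_sims >= 0.75

    def test_temperature_like_scenario_variance_shares(self):
        # annual harmonic ~80% of variance, AR term ~2% more
        from bactoseries.synthetic import decadal_scenario

        periodic, ar_share = [], []
        for seed in range(15):
            spec = decadal_scenario(seed)["temperature"]
            fit = decompose(generate_series(spec))
            assert fit.harmonics
            periodic.append(fit.harmonics[0].pct_variance)
            ar_share.append(fit.ar.pct_variance if fit.ar else 0.0)
        assert np.mean(periodic) == pytest.approx(80.4, abs=5.0)
        assert np.mean(ar_share) == pytest.approx(2.3, abs=1.5)

    def test_missing_months_do_not_break_the_fit(self):
        spec = SeriesSpec(
            n_months=120, mean=15.7, harmonics=((12.0, 3.89, 4.26),),
            noise_sd=1.3, missing_fraction=0.05, seed=9,
        )
        fit = decompose(generate_series(spec))
        assert fit.harmonics
        assert fit.harmonics[0].amplitude == pytest.approx(3.89, rel=0.15)
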