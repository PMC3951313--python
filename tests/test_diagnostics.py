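"""Growth rates, the s amplitude index, ACF/PRCF with Bartlett's band, and
phase-plot geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rookery import (
    SimConfig,
    acf,
    growth_rates,
    phase_trajectory,
    prcf,
    s_index,
    simulate_metapopulation,
)

from conftest import make_series


class TestGrowthRates:
    def test_constant_series_zero_rates(self):
        gr = growth_rates(make_series([500, 500, 500]))
        np.testing.assert_array_equal(gr.rates, [0.0, 0.0])

    def test_doubling_series(self):
        gr = growth_rates(make_series([100, 200, 400]))
        np.testing.assert_allclose(gr.rates, np.log(2), rtol=1e-12)

    def test_gaps_break_transitions(self):
        gr = growth_rates(
            make_series([100, 110, 120, 130], seasons=[1990, 1991, 1994, 1995])
        )
        assert gr.transition_years.tolist() == [1990, 1994]
        assert gr.rates.size == 2

    def test_zero_count_transition_omitted(self):
        gr = growth_rates(make_series([100, 0, 120, 130]))
        assert gr.transition_years.tolist() == [1983]

    @given(scale=st.floats(0.01, 1e4))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        base = make_series([120, 90, 150, 140, 170])
        scaled = make_series(np.asarray([120, 90, 150, 140, 170]) * scale)
        np.testing.assert_allclose(
            growth_rates(base).rates, growth_rates(scaled).rates, atol=1e-10
        )


class TestSIndex:
    def test_two_point_closed_form(self):
        # sample SD of {log10 100, log10 1000} = SD of {2, 3} = 1/sqrt(2)
        assert s_index(make_series([100, 1000])) == pytest.approx(
            1 / np.sqrt(2), rel=1e-12
        )

    def test_constant_series_zero(self):
        assert s_index(make_series([500] * 10)) == 0.0

    def test_one_order_of_magnitude_sinusoid_gives_035(self):
        """A dense sinusoid spanning one decade peak-to-trough has
        s = 1/(2*sqrt(2)) ~ 0.35, the calibration linking s to cycle
        amplitude."""
        t = np.arange(1, 2001)
        s = s_index(make_series(10 ** (2 + 0.5 * np.sin(2 * np.pi * t / 20)),
                                seasons=t))
        assert round(s, 2) == 0.35

    def test_multiplicative_shift_invariance(self):
        a = make_series([120, 90, 150, 140, 170])
        b = make_series(np.asarray([120, 90, 150, 140, 170]) * 37.5)
        assert s_index(a) == pytest.approx(s_index(b), rel=1e-12)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            s_index(make_series([100, 0, 100]))


class TestAcf:
    def test_band_formula(self):
        d = acf(make_series(np.exp(np.linspace(4, 6, 25))), max_lag=5)
        assert d.band == pytest.approx(2 / np.sqrt(25))
        assert d.n == 25

    def test_linear_trend_slow_decay(self):
        """ln-linear series: lag-1 autocorrelation near 1, decaying slowly
        with lag — the ACF signature of a trend rather than a cycle."""
        d = acf(make_series(np.exp(np.linspace(4, 6, 30))), max_lag=8)
        assert d.values[0] > 0.85
        assert np.all(np.diff(d.values) < 0)
        assert np.all(np.abs(d.values) <= 1)

    def test_ar1_large_sample_consistency(self, rng):
        n = 5000
        y = np.empty(n)
        y[0] = 0.0
        for i in range(1, n):
            y[i] = 0.8 * y[i - 1] + rng.normal()
        d = acf(make_series(np.exp(y / 10 + 8), seasons=np.arange(n)), max_lag=3)
        assert 0.77 <= d.values[0] <= 0.83

    def test_constant_series_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            acf(make_series([500] * 20), max_lag=3)

    def test_uses_longest_contiguous_run(self):
        counts = np.concatenate([[200, 210], np.linspace(100, 300, 20)])
        seasons = np.concatenate([[1950, 1951], np.arange(1960, 1980)])
        d = acf(make_series(counts, seasons=seasons), max_lag=5)
        assert d.n == 20


class TestPrcf:
    def test_lag1_equals_pearson_of_rates_vs_lagged_lncounts(self, rng):
        counts = np.exp(rng.normal(8, 0.2, size=30))
        col = make_series(counts)
        d = prcf(col, max_lag=4)
        gr = growth_rates(col)
        expected = np.corrcoef(gr.rates, np.log(counts[:-1]))[0, 1]
        assert d.values[0] == pytest.approx(expected, abs=1e-12)

    def test_gompertz_regulation_detected(self):
        """Strong density dependence (b = -0.5, small noise): lag-1 PRCF is
        negative beyond Bartlett's band."""
        cfg = SimConfig(
            n_colonies=1, log_K=(np.log(40000.0),), b=-0.5, era_drift=(0, 0),
            sigma_env=0.0, sigma_idio=0.05, sigma_obs=0.0,
            seasons=(1900, 1999), seed=42,
        )
        (col,), _ = simulate_metapopulation(cfg)
        d = prcf(col, max_lag=3)
        assert d.values[0] < -d.band

    def test_null_band_coverage_on_drifting_walk(self):
        """No density dependence (random walk with drift, n = 200): the
        lag-1 PRCF exceeds Bartlett's band in at most ~10% of replicates."""
        exceed = 0
        reps = 100
        for rep in range(reps):
            cfg = SimConfig(
                n_colonies=1, log_K=(np.log(40000.0),), b=0.0,
                era_drift=(0.02, 0.02), sigma_env=0.0, sigma_idio=0.1,
                sigma_obs=0.0, seasons=(1800, 2000), seed=5000 + rep,
            )
            (col,), _ = simulate_metapopulation(cfg)
            d = prcf(col, max_lag=1)
            exceed += abs(d.values[0]) > d.band
        assert exceed / reps <= 0.12

    def test_values_bounded(self, rng):
        col = make_series(np.exp(rng.normal(8, 0.3, size=40)))
        d = prcf(col, max_lag=6)
        assert np.all(np.abs(d.values) <= 1)


class TestPhaseTrajectory:
    def test_constant_series_degenerate_orbit(self):
        traj = phase_trajectory(make_series([500] * 6))
        assert np.ptp(traj.points, axis=0).tolist() == [0, 0]
        assert traj.signed_area == 0.0

    def test_monotone_series_above_diagonal(self):
        traj = phase_trajectory(make_series([100, 120, 150, 190, 240]))
        assert np.all(traj.points[:, 1] > traj.points[:, 0])

    def test_delayed_density_dependence_gives_consistent_orbit(self):
        """A noiseless second-order log-linear model with complex eigenvalues
        orbits its equilibrium with a constant rotation sense."""
        # x_{t+1} = 1.6 x_t - 0.9 x_{t-1}: eigenvalues 0.8 +- 0.51i
        x = np.empty(60)
        x[0], x[1] = 0.5, 0.4
        for t in range(1, 59):
            x[t + 1] = 1.6 * x[t] - 0.9 * x[t - 1]
        traj = phase_trajectory(make_series(np.exp(8 + x), seasons=np.arange(60)))
        disp = np.diff(traj.points, axis=0)
        cross = disp[:-1, 0] * disp[1:, 1] - disp[:-1, 1] * disp[1:, 0]
        assert traj.signed_area != 0.0
        assert np.all(np.sign(cross[np.abs(cross) > 1e-12]) ==
                      np.sign(traj.signed_area))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            phase_trajectory(make_series([100, 110, 120]))
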