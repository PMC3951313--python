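"""Exact-ML AR(1) GLS trend fits, AICc selection, and aggregate growth."""

import numpy as np
import pytest

from rookery import (
    aicc,
    fit_gls_ar1,
    metapopulation_growth,
    select_trend_model,
    simulate_ar1_trend,
)
from rookery.trends import _designs, _profile_loglik

from conftest import make_series


def _single_design(years):
    return _designs(np.asarray(years, dtype=float), 10**9)[0]


def brute_force_ml(years, y, X, grid_n=1961):
    """Independent oracle: dense profile-likelihood grid over phi."""
    years = np.asarray(years, dtype=float)
    grid = np.linspace(-0.98, 0.98, grid_n)
    lls = [_profile_loglik(p, years, y, X)[0] for p in grid]
    i = int(np.argmax(lls))
    _, beta, _, _ = _profile_loglik(grid[i], years, y, X)
    return grid[i], beta


class TestFitGlsAr1:
    def test_noiseless_linear_recovery(self):
        years = np.arange(1981, 2001)
        y = 3.0 + 0.05 * (years - 1981)
        fit = fit_gls_ar1(years, y, _single_design(years))
        assert fit.coefficients[1] == pytest.approx(0.05, abs=1e-10)
        assert fit.sigma2 <= 1e-10

    def test_phi_zero_reduces_to_ols(self, rng):
        years = np.arange(1981, 2011)
        y = 3 + 0.02 * (years - 1981) + rng.normal(0, 0.1, years.size)
        X = _single_design(years)
        fit = fit_gls_ar1(years, y, X, phi=0.0)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, beta_ols, rtol=1e-10)

    def test_matches_brute_force_grid_oracle(self, rng):
        years = np.arange(1981, 2181)
        y = simulate_ar1_trend(years, [5.0, 0.05], 0.6, 0.1, rng)
        X = _single_design(years)
        fit = fit_gls_ar1(years, y, X)
        phi0, beta0 = brute_force_ml(years, y, X)
        assert fit.phi == pytest.approx(phi0, abs=1e-3)
        assert fit.coefficients[1] == pytest.approx(beta0[1], abs=1e-3)

    def test_gapfree_likelihood_equals_prais_winsten_whitening(self, rng):
        """For annual (gap-free) data the exact AR(1) likelihood must agree
        with the classic Prais-Winsten whitening-transform likelihood."""
        years = np.arange(1981, 2011)
        y = simulate_ar1_trend(years, [4.0, 0.03], 0.5, 0.08, rng)
        X = _single_design(years)
        phi = 0.47
        ll, beta, sigma2, _ = _profile_loglik(phi, years.astype(float), y, X)
        # whiten: first row scaled by sqrt(1-phi^2), others y_t - phi y_{t-1}
        n = years.size
        T = np.eye(n)
        T[0, 0] = np.sqrt(1 - phi**2)
        for i in range(1, n):
            T[i, i - 1] = -phi
        ys, Xs = T @ y, T @ X
        beta_w = np.linalg.lstsq(Xs, ys, rcond=None)[0]
        resid = ys - Xs @ beta_w
        # whitened errors are iid N(0, sigma2); |det T| = sqrt(1-phi^2)
        s2 = resid @ resid / n
        ll_w = -0.5 * n * np.log(2 * np.pi * s2) + 0.5 * np.log(1 - phi**2) - 0.5 * n
        np.testing.assert_allclose(beta, beta_w, rtol=1e-10)
        assert ll == pytest.approx(ll_w, abs=1e-10)

    def test_year_shift_changes_intercept_only(self, rng):
        years = np.arange(1981, 2013)
        y = simulate_ar1_trend(years, [4.0, 0.03], 0.4, 0.05, rng)
        a = fit_gls_ar1(years, y, _single_design(years))
        b = fit_gls_ar1(years + 500, y, _single_design(years + 500))
        assert a.coefficients[1] == pytest.approx(b.coefficients[1], abs=1e-8)
        assert a.phi == pytest.approx(b.phi, abs=1e-6)
        assert a.aicc == pytest.approx(b.aicc, abs=1e-8)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            fit_gls_ar1(np.arange(4), np.ones(4), _single_design(np.arange(4)))


class TestAicc:
    @pytest.mark.parametrize(
        "ll,k,n,expected", [(-10, 4, 30, 29.6), (0, 6, 28, 16.0)]
    )
    def test_formula(self, ll, k, n, expected):
        assert aicc(ll, k, n) == pytest.approx(expected)

    def test_orders_like_negative_loglik(self):
        assert aicc(-5, 4, 30) < aicc(-8, 4, 30)

    def test_undefined_below_minimum_n(self):
        with pytest.raises(ValueError):
            aicc(-10, 4, 5)


class TestSelectTrendModel:
    def test_noiseless_single_slope_picks_single(self):
        years = np.arange(1981, 2013)
        col = make_series(np.exp(3 + 0.02 * (years - 1981)), seasons=years)
        winner, single, piece = select_trend_model(col)
        assert winner.model_kind == "single"
        assert piece is not None  # both fitted and returned

    def test_piecewise_recovery_at_published_magnitudes(self, rng):
        """Slopes of -0.02 then +0.08 with AR(1) noise: the two-trend model
        should win AICc in >= 90% of replicates with era-2 slope nearly
        unbiased."""
        years = np.arange(1981, 2013)
        wins, slopes2 = 0, []
        for _ in range(50):
            y = simulate_ar1_trend(
                years, [8.0, -0.02, 8.0 - 0.08 * 20, 0.08], 0.3, 0.05, rng,
                breakpoint_year=2001,
            )
            col = make_series(np.exp(y), seasons=years)
            winner, _, piece = select_trend_model(col)
            if winner.model_kind == "piecewise":
                wins += 1
            slopes2.append(piece.coefficients[3])
        assert wins >= 45
        assert abs(np.mean(slopes2) - 0.08) < 0.01

    def test_white_noise_mostly_picks_single(self, rng):
        years = np.arange(1981, 2013)
        wins = 0
        for _ in range(50):
            col = make_series(np.exp(rng.normal(8, 0.1, years.size)),
                              seasons=years)
            winner, _, _ = select_trend_model(col)
            wins += winner.model_kind == "single"
        assert wins > 25

    def test_sparse_era_skips_piecewise(self):
        years = np.concatenate([np.arange(1981, 2001), [2005, 2008, 2010]])
        col = make_series(np.exp(np.linspace(8, 8.5, years.size)), seasons=years)
        winner, single, piece = select_trend_model(col)
        assert piece is None
        assert winner is single


class TestMetapopulationGrowth:
    def test_single_transition(self):
        col = make_series([100, 110])
        assert metapopulation_growth([col], (1981, 1982)) == pytest.approx(
            np.log(1.1)
        )

    def test_two_identical_colonies_same_rate(self):
        a = make_series([100, 110, 125], colony_id="a")
        b = make_series([100, 110, 125], colony_id="b")
        assert metapopulation_growth([a, b], (1981, 1983)) == pytest.approx(
            metapopulation_growth([a], (1981, 1983))
        )

    def test_common_slope_recovered_exactly(self):
        years = np.arange(2001, 2013)
        cols = [
            make_series(k * np.exp(0.067 * (years - 2001)), seasons=years,
                        colony_id=str(k))
            for k in (2825, 43321, 153632, 39391)
        ]
        assert metapopulation_growth(cols, (2001, 2012)) == pytest.approx(
            0.067, abs=1e-12
        )

    def test_missing_member_drops_season(self):
        a = make_series([100, 110, 120, 130])
        b = make_series([50, np.nan, 60, 65], colony_id="b")
        # shared seasons 1981, 1983, 1984 -> only the 1983->84 transition
        rate = metapopulation_growth([a, b], (1981, 1984))
        assert rate == pytest.approx(np.log((130 + 65) / (120 + 60)))
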