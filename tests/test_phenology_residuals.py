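"""Bilinear phenology de-trending and residual/quantile regressions."""

import numpy as np
import pytest
from scipy import stats

from bnfcurve import (
    DomainError,
    InsufficientDataError,
    fit_bilinear,
    residual_mean_regression,
    residual_quantile_regression,
)


def bilinear(x, a, b, d, tt_o):
    return b + a * np.minimum(x, tt_o) + d * np.maximum(x - tt_o, 0.0)


class TestFitBilinear:
    def test_exact_recovery(self):
        x = np.linspace(900, 1700, 41)  # grid contains tt_o = 1200
        y = bilinear(x, a=2.0, b=100.0, d=0.3, tt_o=1200.0)
        fit = fit_bilinear(x, y)
        assert fit.a == pytest.approx(2.0, abs=1e-6)
        assert fit.b == pytest.approx(100.0, abs=1e-4)
        assert fit.d == pytest.approx(0.3, abs=1e-6)
        assert fit.tt_o == pytest.approx(1200.0)
        assert np.max(np.abs(fit.residuals)) < 1e-8

    def test_constant_trait(self):
        x = np.linspace(900, 1700, 20)
        fit = fit_bilinear(x, np.full(20, 5000.0))
        assert fit.a == pytest.approx(0.0, abs=1e-9)
        assert fit.d == pytest.approx(0.0, abs=1e-9)
        assert np.max(np.abs(fit.residuals)) < 1e-8

    def test_continuity_at_breakpoint(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(900, 1700, 92)
        y = bilinear(x, 3.0, 1500.0, 0.5, 1300.0) + rng.normal(0, 150, 92)
        fit = fit_bilinear(x, y)
        seg1_at_knot = fit.b + fit.a * fit.tt_o
        seg2_at_knot = fit.predict(fit.tt_o)
        assert abs(seg1_at_knot - seg2_at_knot) < 1e-9 * np.ptp(y)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(900, 1700, 60)
        y = bilinear(x, 3.0, 1500.0, 0.5, 1300.0) + rng.normal(0, 100, 60)
        fit = fit_bilinear(x, y)
        assert abs(fit.residuals.sum()) < 1e-6 * np.abs(y).sum()

    def test_detrending_idempotent(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(900, 1700, 92)
        y = bilinear(x, 3.0, 1500.0, 0.5, 1300.0) + rng.normal(0, 100, 92)
        resid = fit_bilinear(x, y).residuals
        refit = fit_bilinear(x, resid)
        # no phenology trend remains: the refit explains almost nothing
        assert refit.r2 < 0.1
        assert np.std(refit.residuals) == pytest.approx(np.std(resid), rel=0.1)

    def test_breakpoint_recovery_monte_carlo(self):
        """With noise at 5% of the trait range on 92 points, the profiled
        breakpoint lands within one grid step of the truth in >= 80% of
        seeded replicates."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(4000 + rep)
            x = np.sort(rng.uniform(900, 1700, 92))
            x[np.argmin(np.abs(x - 1300.0))] = 1300.0  # truth on the grid
            # rise then plateau, the shape of yield vs season length
            y_clean = bilinear(x, 3.0, 1500.0, 0.0, 1300.0)
            y = y_clean + rng.normal(0, 0.05 * np.ptp(y_clean), 92)
            fit = fit_bilinear(x, y)
            i = int(np.searchsorted(x, 1300.0))
            neighbors = x[max(i - 1, 0): i + 2]
            hits += neighbors.min() <= fit.tt_o <= neighbors.max()
        assert hits >= 0.80 * n_rep

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_bilinear(np.arange(5.0), np.arange(5.0))


class TestResidualMeanRegression:
    def test_constructed_slope(self):
        rng = np.random.default_rng(8)
        rau = rng.uniform(40, 95, 92)
        resid = -13.0 * (rau - rau.mean())
        reg = residual_mean_regression(resid, rau)
        assert reg.slope == pytest.approx(-13.0, abs=1e-9)
        assert reg.p_value < 1e-12

    def test_null_case(self):
        rng = np.random.default_rng(9)
        rau = rng.uniform(40, 95, 92)
        resid = rng.normal(0, 200, 92)
        reg = residual_mean_regression(resid, rau)
        lr = stats.linregress(rau, resid)  # independent oracle for slope + SE
        assert reg.slope == pytest.approx(lr.slope, rel=1e-9)
        assert abs(reg.slope) <= 3 * lr.stderr

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            residual_mean_regression(np.arange(10.0), np.full(10, 70.0))


class TestResidualQuantileRegression:
    def test_median_close_to_ols_under_symmetry(self):
        rng = np.random.default_rng(10)
        rau = rng.uniform(40, 95, 300)
        resid = -5.0 * (rau - rau.mean()) + rng.normal(0, 50, 300)
        q = residual_quantile_regression(resid, rau, 0.5)
        m = residual_mean_regression(resid, rau)
        assert q.slope == pytest.approx(m.slope, abs=0.5)

    def test_exact_line_any_tau(self):
        rau = np.linspace(40, 95, 60)
        resid = 2.0 * rau - 50.0
        for tau in (0.1, 0.5, 0.9):
            q = residual_quantile_regression(resid, rau, tau)
            assert q.slope == pytest.approx(2.0, abs=1e-6)
            assert q.intercept == pytest.approx(-50.0, abs=1e-4)

    def test_lower_boundary_steeper_under_heteroscedasticity(self):
        """When the lower response boundary falls 2.5x faster than the
        mean, the 0.01-quantile slope over the mean slope lands in [2, 3]."""
        ratios = []
        for rep in range(10):
            rng = np.random.default_rng(5000 + rep)
            rau = rng.uniform(0, 100, 400)
            # boundary slope -5, mean slope -2: y = -5x + 3x*V, V ~ U(0, 2)
            y = -5.0 * rau + 3.0 * rau * rng.uniform(0, 2, 400)
            q = residual_quantile_regression(y, rau, 0.01)
            m = residual_mean_regression(y, rau)
            ratios.append(q.slope / m.slope)
        assert 2.0 <= np.mean(ratios) <= 3.0

    def test_quantile_lines_bracket_mean_under_exchangeable_noise(self):
        rng = np.random.default_rng(13)
        rau = rng.uniform(40, 95, 500)
        resid = rng.normal(0, 100, 500)
        q_lo = residual_quantile_regression(resid, rau, 0.01)
        q_hi = residual_quantile_regression(resid, rau, 0.99)
        m = residual_mean_regression(resid, rau)
        grid = np.linspace(rau.min(), rau.max(), 50)
        assert np.all(q_hi.predict(grid) >= q_lo.predict(grid))
        assert np.all(q_hi.predict(grid) >= m.predict(grid))
        assert np.all(m.predict(grid) >= q_lo.predict(grid))

    def test_upper_quantile_lies_above_99pct_of_points(self):
        rng = np.random.default_rng(14)
        rau = rng.uniform(40, 95, 500)
        resid = rng.normal(0, 80, 500)
        q = residual_quantile_regression(resid, rau, 0.99)
        frac_below = np.mean(resid <= q.predict(rau) + 1e-9)
        assert frac_below >= 0.98

    def test_tau_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            residual_quantile_regression(np.zeros(30), np.arange(30.0), 1.5)
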