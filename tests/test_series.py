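"""Spline alignment, gap masking, trapezoid cumulation and Monte Carlo."""

import numpy as np
import pandas as pd
import pytest

from pulsechase import (
    cumulate_trapezoid,
    fit_smoothing_spline,
    mc_cumulative_uncertainty,
    replicate_mean_infill,
    resample_to_grid,
)
from pulsechase.series import (
    DEFAULT_SMOOTHING,
    MASK_MASKED,
    MASK_OBSERVED,
    MASK_REPLICATE,
    FluxSeries,
)

from conftest import T0


def make_series(grid, values, sds=None, mask=None, variable="abs13c", mid="M01"):
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    sds = np.zeros_like(values) if sds is None else np.asarray(sds, dtype=float)
    if mask is None:
        mask = np.where(np.isnan(values), MASK_MASKED, MASK_OBSERVED).astype(object)
    return FluxSeries(mid, variable, grid, values, sds, np.asarray(mask, dtype=object), T0)


class TestSmoothingSpline:
    @pytest.mark.parametrize("lam", [0.0, 1e-6, DEFAULT_SMOOTHING, 0.1])
    def test_line_reproduced_for_any_penalty(self, lam):
        # a straight line lies in the null space of the roughness penalty
        t = np.linspace(0, 48, 40)
        y = 2.0 * t + 1.0
        fit = fit_smoothing_spline(t, y, smoothing=lam)
        pred = fit(np.linspace(1, 47, 100))
        truth = 2.0 * np.linspace(1, 47, 100) + 1.0
        assert np.max(np.abs(pred / truth - 1)) < 1e-8

    def test_cubic_exact_at_zero_penalty(self):
        t = np.linspace(0, 10, 25)
        y = t**3 - 2 * t**2 + 4
        fit = fit_smoothing_spline(t, y, smoothing=0.0)
        x = np.linspace(0.5, 9.5, 50)
        assert np.allclose(fit(x), x**3 - 2 * x**2 + 4, rtol=1e-8, atol=1e-8)

    def test_noisy_sinusoid_rmse(self):
        rng = np.random.default_rng(7)
        t = np.sort(rng.uniform(0, 96, 200))
        truth = np.sin(2 * np.pi * t / 24.0)
        y = truth + rng.normal(0, 0.01, len(t))
        fit = fit_smoothing_spline(t, y, smoothing=DEFAULT_SMOOTHING)
        x = np.linspace(2, 94, 300)
        rmse = np.sqrt(np.mean((fit(x) - np.sin(2 * np.pi * x / 24.0)) ** 2))
        assert rmse < 0.02

    def test_few_points_linear_fallback(self):
        fit = fit_smoothing_spline([0.0, 1.0, 2.0], [0.0, 2.0, 4.0])
        assert fit.fallback_linear
        assert fit(1.5) == pytest.approx(3.0)


class TestResampleToGrid:
    def _fit(self, t, y, sds=None):
        return fit_smoothing_spline(t, y, sds, smoothing=0.0)

    def test_dense_observations_no_masking(self):
        t = np.arange(0, 49, 2.0)
        fit = self._fit(t, 2 * t)
        s = resample_to_grid(fit, "M01", "sr", T0, step_h=2.0, max_gap_h=6.0)
        assert not np.isnan(s.values).any()
        assert (s.mask == MASK_OBSERVED).all()

    def test_eight_hour_gap_masked(self):
        t = np.array([0, 2, 4, 6, 14, 16, 18.0])  # 8-h gap between 6 and 14
        fit = self._fit(t, np.ones_like(t))
        s = resample_to_grid(fit, "M01", "sr", T0, step_h=2.0, max_gap_h=6.0)
        interior = (s.grid > 6) & (s.grid < 14)
        assert np.isnan(s.values[interior]).all()
        assert (s.mask[interior] == MASK_MASKED).all()

    def test_six_hour_gap_filled_boundary_inclusive(self):
        t = np.array([0, 2, 4, 6, 12, 14.0])  # exactly 6-h gap
        fit = self._fit(t, np.ones_like(t))
        s = resample_to_grid(fit, "M01", "sr", T0, step_h=2.0, max_gap_h=6.0)
        assert not np.isnan(s.values).any()

    def test_no_extrapolation_outside_span(self):
        t = np.array([3.0, 5, 7, 9])
        fit = self._fit(t, np.ones_like(t))
        s = resample_to_grid(fit, "M01", "sr", T0, step_h=2.0, max_gap_h=6.0,
                             grid_start_h=0.0, grid_end_h=12.0)
        outside = (s.grid < 3) | (s.grid > 9)
        assert np.isnan(s.values[outside]).all()

    def test_sd_from_nearest_observation(self):
        t = np.array([0.0, 2, 4, 6])
        sds = np.array([1.0, 2.0, 3.0, 4.0])
        fit = self._fit(t, np.ones_like(t), sds)
        s = resample_to_grid(fit, "M01", "sr", T0, step_h=2.0)
        assert s.sds[0] == 1.0 and s.sds[-1] == 4.0


class TestCumulateTrapezoid:
    def test_constant_rate(self):
        grid = np.arange(0, 121, 2.0)
        c = cumulate_trapezoid(make_series(grid, np.ones_like(grid)), (0.0, 120.0))
        assert c.total == pytest.approx(120.0, rel=1e-12)
        assert c.fill_fraction == 0.0

    def test_linear_ramp_exact(self):
        grid = np.arange(0, 25, 2.0)
        a, b = 3.0, 0.5
        c = cumulate_trapezoid(make_series(grid, a + b * grid), (0.0, 24.0))
        assert c.total == pytest.approx(a * 24 + b * 24**2 / 2, rel=1e-12)

    def test_partial_window_clipping(self):
        grid = np.arange(0, 25, 2.0)
        c = cumulate_trapezoid(make_series(grid, np.ones_like(grid)), (1.0, 23.0))
        assert c.total == pytest.approx(22.0, rel=1e-12)

    def test_masked_run_equals_linear_bridge(self):
        """Masked interior run vs the same series with the bridge values
        written in explicitly: identical totals."""
        grid = np.arange(0, 25, 2.0)
        values = 5.0 + 0.25 * grid
        masked = values.copy()
        masked[4:8] = np.nan  # gap from t=8 to t=14
        c_masked = cumulate_trapezoid(make_series(grid, masked), (0.0, 24.0))
        bridge = values.copy()
        bridge[4:8] = np.interp(grid[4:8], [grid[3], grid[8]],
                                [values[3], values[8]])
        c_bridge = cumulate_trapezoid(make_series(grid, bridge), (0.0, 24.0))
        assert c_masked.total == pytest.approx(c_bridge.total, rel=1e-12)
        assert c_masked.fill_fraction > 0

    def test_fully_masked_window_errors(self):
        grid = np.arange(0, 25, 2.0)
        values = np.full_like(grid, np.nan)
        values[:2] = 1.0
        with pytest.raises(ValueError):
            cumulate_trapezoid(make_series(grid, values), (10.0, 20.0))


class TestReplicateMeanInfill:
    def _with_gap(self, level, gap=(8.0, 16.0)):
        grid = np.arange(0, 25, 2.0)
        values = np.full_like(grid, float(level))
        values[(grid > gap[0]) & (grid < gap[1])] = np.nan
        return make_series(grid, values)

    def _replicate(self, level):
        grid = np.arange(0, 25, 2.0)
        return make_series(grid, np.full_like(grid, float(level)), mid="rep")

    def test_mean_of_equal_replicates(self):
        target = self._with_gap(1.0)
        reps = [self._replicate(10.0 / 8.0), self._replicate(10.0 / 8.0)]
        filled = replicate_mean_infill(target, reps, (8.0, 16.0))
        assert filled.replicate_fills == [(8.0, 16.0, pytest.approx(10.0))]

    def test_mean_of_unequal_replicates(self):
        target = self._with_gap(1.0)
        reps = [self._replicate(1.0), self._replicate(1.5)]  # 8 and 12 over 8 h
        filled = replicate_mean_infill(target, reps, (8.0, 16.0))
        assert filled.replicate_fills[0][2] == pytest.approx(10.0)
        assert (filled.mask[(filled.grid > 8) & (filled.grid < 16)]
                == MASK_REPLICATE).all()

    def test_no_covering_replicate_leaves_gap(self):
        target = self._with_gap(1.0)
        rep = self._with_gap(1.0)  # replicate has the same gap
        filled = replicate_mean_infill(target, [rep], (8.0, 16.0))
        assert filled.replicate_fills == []

    def test_preserves_replicate_mean_total_exactly(self):
        target = self._with_gap(1.0)
        reps = [self._replicate(2.0), self._replicate(4.0)]
        filled = replicate_mean_infill(target, reps, (8.0, 16.0))
        c = cumulate_trapezoid(filled, (8.0, 16.0))
        assert c.total == pytest.approx(3.0 * 8.0, rel=1e-12)


class TestMonteCarlo:
    def test_zero_sds_zero_spread(self):
        grid = np.arange(0, 25, 2.0)
        s = make_series(grid, np.ones_like(grid))
        mc_sd, (lo, hi) = mc_cumulative_uncertainty(s, (0.0, 24.0), n=200, seed=1)
        assert mc_sd == 0.0 and lo == hi == pytest.approx(24.0)

    def test_matches_weight_vector_closed_form(self):
        """Independent-normal draws through a fixed trapezoid weight vector:
        sd = sigma * h * sqrt(2*(1/2)^2 + (m-2))."""
        h, m, sigma = 2.0, 13, 0.5
        grid = h * np.arange(m)
        s = make_series(grid, np.full(m, 3.0), sds=np.full(m, sigma))
        mc_sd, _ = mc_cumulative_uncertainty(s, (grid[0], grid[-1]), n=1000, seed=2)
        closed = sigma * h * np.sqrt(2 * 0.25 + (m - 2))
        assert mc_sd == pytest.approx(closed, rel=0.10)

    def test_seed_reproducibility(self):
        grid = np.arange(0, 25, 2.0)
        s = make_series(grid, np.ones_like(grid), sds=np.full_like(grid, 0.3))
        a = mc_cumulative_uncertainty(s, (0.0, 24.0), n=500, seed=5)
        b = mc_cumulative_uncertainty(s, (0.0, 24.0), n=500, seed=5)
        assert a == b

    def test_mc_mean_converges_to_deterministic_total(self):
        rng_grid = np.arange(0, 49, 2.0)
        values = 2.0 + np.sin(rng_grid / 5.0)
        s = make_series(rng_grid, values, sds=np.full_like(rng_grid, 0.4))
        n = 2000
        det = cumulate_trapezoid(s, (0.0, 48.0)).total
        rng = np.random.default_rng(3)
        from pulsechase.series import _trapezoid_weights, _window_nodes
        t, v, sd, _, _ = _window_nodes(s, (0.0, 48.0))
        draws = rng.normal(v, sd, size=(n, len(v)))
        totals = draws @ _trapezoid_weights(t)
        mc_sd = totals.std(ddof=1)
        assert abs(totals.mean() - det) < 3 * mc_sd / np.sqrt(n)
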