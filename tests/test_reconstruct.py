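"""Spline smoothing and ODE-inversion reconstruction of transcription."""

import numpy as np
import pytest

import txcycle as tx
from txcycle.datatypes import CellTrace, DataError
from txcycle.reconstruct import (
    FINE_STEP,
    fit_protein_spline,
    reconstruct_cell,
    reconstruct_mrna,
    reconstruct_transcription,
    trim_boundary,
)


def _trace(t, y):
    return CellTrace("c", "luc", np.asarray(t, float), np.asarray(y, float))


class TestSpline:
    def test_reproduces_cubic_polynomial(self):
        t = np.linspace(0.0, 10.0, 25)
        y = 0.3 * t**3 - 2 * t**2 + t + 5
        # zero penalty interpolates the noiseless samples exactly
        fit = fit_protein_spline(_trace(t, y), smoothing=0.0)
        np.testing.assert_allclose(fit.fitted(t), y, atol=1e-8 * np.abs(y).max())
        # GCV keeps a small penalty but stays very close on noiseless data
        fit_gcv = fit_protein_spline(_trace(t, y))
        np.testing.assert_allclose(fit_gcv.fitted(t), y, atol=1e-3 * np.abs(y).max())

    def test_constant_trace_has_zero_derivative(self):
        t = np.linspace(0.0, 12.0, 20)
        fit = fit_protein_spline(_trace(t, np.full(20, 3.0)))
        np.testing.assert_allclose(fit.derivative(t), 0.0, atol=1e-8)

    def test_noisy_sine_rmse_below_noise_sd(self, rng):
        t = np.linspace(0.0, 24.0, 30)
        true = 10 + 5 * np.sin(2 * np.pi * t / 12.0)
        sd = 0.05 * true.mean()
        y = true + rng.normal(0, sd, size=t.shape)
        fit = fit_protein_spline(_trace(t, y))
        rmse = np.sqrt(np.mean((fit.fitted(t) - true) ** 2))
        assert rmse < sd

    def test_too_few_points_and_duplicates_rejected(self):
        with pytest.raises(DataError):
            fit_protein_spline(_trace(np.arange(5), np.arange(5.0)))
        t = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8.0])
        tr = _trace(t, t)
        tr.times = tr.times.copy()
        tr.times[3] = tr.times[2]  # duplicate after construction
        with pytest.raises(DataError):
            fit_protein_spline(tr)

    def test_evaluation_outside_support_errors(self):
        t = np.linspace(0.0, 10.0, 12)
        fit = fit_protein_spline(_trace(t, t**2))
        with pytest.raises(DataError):
            fit.fitted(11.0)


class TestInversion:
    def test_steady_state_gives_delta_p_times_p(self):
        t = np.linspace(0.0, 15.0, 20)
        fit = fit_protein_spline(_trace(t, np.full(20, 8.0)))
        grid, am = reconstruct_mrna(fit, delta_p=0.35)
        np.testing.assert_allclose(am, 0.35 * 8.0, atol=1e-8)

    def test_zero_delta_p_returns_pure_derivative(self):
        t = np.linspace(0.0, 10.0, 20)
        fit = fit_protein_spline(_trace(t, 2.0 * t))
        _, am = reconstruct_mrna(fit, delta_p=0.0)
        np.testing.assert_allclose(am, 2.0, atol=1e-7)

    def test_constant_mrna_gives_delta_m_times_m(self):
        grid = np.arange(0.0, 5.0, 0.1)
        prof = reconstruct_transcription(grid, np.full(grid.size, 4.0), delta_m=0.7)
        np.testing.assert_allclose(prof.tau, 2.8, atol=1e-12)
        assert prof.grid.size == grid.size - 1  # last point dropped

    def test_zero_delta_m_gives_discrete_derivative(self):
        grid = np.arange(0.0, 5.0, 0.1)
        m = 3.0 * grid
        prof = reconstruct_transcription(grid, m, delta_m=0.0)
        np.testing.assert_allclose(prof.tau, 3.0, atol=1e-9)

    def test_non_uniform_grid_rejected(self):
        grid = np.array([0.0, 0.1, 0.25, 0.3])
        with pytest.raises(DataError):
            reconstruct_transcription(grid, np.ones(4), 0.5)


class TestRoundTrip:
    def test_single_pulse_recovery(self, single_pulse_path, luc_kin, hourly_grid):
        """Noiseless simulate -> reconstruct recovers the binary rate path."""
        trace = tx.simulate_reporter(
            single_pulse_path, luc_kin, tx.NoiseParams(), hourly_grid
        )
        prof = reconstruct_cell(trace, luc_kin)
        assert prof.step == pytest.approx(FINE_STEP)
        true_tau = single_pulse_path.rate_at(prof.grid)
        # pulse interior (clear of the ~1-h smoothing shoulders): within
        # 10% of beta_on
        interior = (prof.grid > 9.5) & (prof.grid < 10.5)
        assert np.all(np.abs(prof.tau[interior] - 10.0) < 1.0)
        # far outside the pulse: near zero
        outside = (prof.grid > 2.0) & (prof.grid < 6.0)
        assert np.all(np.abs(prof.tau[outside]) < 1.0)
        # relative L2 error away from boundaries and jump neighborhoods
        # (a smoothing spline cannot resolve the discontinuities themselves)
        keep = (prof.grid > 1.0) & (prof.grid < 29.0)
        for s_t in single_pulse_path.switch_times:
            keep &= np.abs(prof.grid - s_t) > 1.0
        rel = np.linalg.norm(prof.tau[keep] - true_tau[keep]) / np.linalg.norm(
            true_tau[keep]
        )
        assert rel < 0.10

    def test_calibrated_cells_round_trip(self, small_population, luc_kin):
        """Noiseless traces from calibrated switch paths round-trip within 10%."""
        for cell in small_population.cells[:3]:
            trace = tx.simulate_reporter(
                cell.path_luc, luc_kin, tx.NoiseParams(),
                np.arange(0.0, 30.0 + 1e-9, 0.5),
            )
            prof = reconstruct_cell(trace, luc_kin)
            keep = (prof.grid > 1.0) & (prof.grid < 29.0)
            for s_t in cell.path_luc.switch_times:
                keep &= np.abs(prof.grid - s_t) > 1.0
            true_tau = cell.path_luc.rate_at(prof.grid)
            rel = np.linalg.norm(prof.tau[keep] - true_tau[keep]) / np.linalg.norm(
                true_tau[keep]
            )
            assert rel < 0.10

    def test_reconstruction_is_linear(self, single_pulse_path, luc_kin, hourly_grid):
        tr1 = tx.simulate_reporter(
            single_pulse_path, luc_kin, tx.NoiseParams(), hourly_grid
        )
        path2 = tx.SwitchPath(np.array([15.0, 20.0]), "off", (0.0, 6.0), 30.0)
        tr2 = tx.simulate_reporter(path2, luc_kin, tx.NoiseParams(), hourly_grid)
        a, b = 2.0, 0.7
        combo = CellTrace("c", "luc", hourly_grid, a * tr1.values + b * tr2.values)
        # linearity holds for a fixed smoothing penalty (GCV would adapt)
        lam = 1e-3
        p1 = reconstruct_cell(tr1, luc_kin, smoothing=lam)
        p2 = reconstruct_cell(tr2, luc_kin, smoothing=lam)
        pc = reconstruct_cell(combo, luc_kin, smoothing=lam)
        np.testing.assert_allclose(pc.tau, a * p1.tau + b * p2.tau, rtol=1e-6, atol=1e-8)

    def test_dual_shared_noiseless_profiles_agree(self, calibrated, luc_kin, gfp_kin):
        from scipy.stats import spearmanr

        cell = tx.simulate_dual_cell(
            calibrated, luc_kin, gfp_kin, coupling="shared",
            noise=tx.NoiseParams(), seed=3,
        )
        p_luc = trim_boundary(reconstruct_cell(cell.luc, luc_kin))
        p_gfp = trim_boundary(reconstruct_cell(cell.gfp, gfp_kin))
        common = p_luc.grid[(p_luc.grid >= p_gfp.grid[0]) & (p_luc.grid <= p_gfp.grid[-1])]
        a = np.interp(common, p_luc.grid, p_luc.tau)
        b = np.interp(common, p_gfp.grid, p_gfp.tau)
        assert spearmanr(a, b).statistic > 0.95
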