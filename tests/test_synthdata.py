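"""Generator: switch-path statistics, exact ODE integration, determinism."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import solve_ivp

import txcycle as tx
from txcycle.datatypes import ParameterError, DataError
from txcycle.synthdata import sample_stimulated_path


def _pooled_intervals(params, duration, seeds):
    ons, offs = [], []
    for s in seeds:
        path = tx.sample_switch_path(params, duration, seed=s)
        for start, end, state in path.intervals()[1:-1]:  # interior only
            (ons if state == "on" else offs).append(end - start)
    return np.array(ons), np.array(offs)


class TestSwitchPath:
    def test_refractory_floor_and_mean_off(self, calibrated):
        # long records keep the interior-interval censoring bias negligible
        ons, offs = _pooled_intervals(calibrated, 2000.0, range(40))
        assert offs.size > 5000
        assert np.all(offs >= calibrated.refractory)
        # mean off = refractory + mean excess = 6.5 h, mean on = 4.0 h
        assert np.mean(offs) == pytest.approx(6.5, abs=4 * offs.std() / np.sqrt(offs.size))
        assert np.mean(ons) == pytest.approx(4.0, abs=4 * ons.std() / np.sqrt(ons.size))

    def test_off_times_exponential_without_refractory(self):
        params = tx.SwitchParams(
            mean_on=4.0, refractory=0.0, mean_excess_off=3.5, rate_on=10.0
        )
        _, offs = _pooled_intervals(params, 500.0, range(200))
        d = stats.kstest(offs, stats.expon(scale=3.5).cdf)
        assert d.pvalue > 0.05

    def test_alternation_and_ordering(self, calibrated):
        path = tx.sample_switch_path(calibrated, 50.0, seed=7)
        assert np.all(np.diff(path.switch_times) > 0)
        states = path.states()
        assert all(a != b for a, b in zip(states, states[1:]))

    def test_invalid_parameters_raise(self, calibrated):
        with pytest.raises(ParameterError):
            tx.sample_switch_path(calibrated, -1.0)
        with pytest.raises(ParameterError):
            tx.SwitchParams(mean_on=-1, refractory=0, mean_excess_off=1, rate_on=1)
        with pytest.raises(ParameterError):
            tx.SwitchParams(mean_on=1, refractory=0, mean_excess_off=1,
                            rate_on=1.0, rate_off=2.0)

    def test_stimulated_path_starts_off_and_activates_after_stimulus(self, calibrated):
        path = sample_stimulated_path(calibrated, 21.0, 2.0, seed=3)
        assert path.initial_state == "off"
        assert 2.0 <= path.switch_times[0] <= 2.5


class TestSimulateReporter:
    def test_pure_decay_closed_form(self, luc_kin):
        # tau = 0 everywhere: M and P decay as the homogeneous solution
        path = tx.SwitchPath(np.empty(0), "off", (0.0, 1.0), 20.0)
        grid = np.linspace(0.0, 20.0, 41)
        m0, p0 = 5.0, 12.0
        trace = tx.simulate_reporter(
            path, luc_kin, tx.NoiseParams(), grid, m0=m0, p0=p0
        )
        dm, dp, a = luc_kin.delta_M, luc_kin.delta_P, luc_kin.alpha
        expect = (
            a * m0 / (dp - dm) * (np.exp(-dm * grid) - np.exp(-dp * grid))
            + p0 * np.exp(-dp * grid)
        )
        np.testing.assert_allclose(trace.values, expect, rtol=1e-12)

    def test_steady_state(self, luc_kin):
        tau = 7.0
        path = tx.SwitchPath(np.empty(0), "on", (0.0, tau), 200.0)
        grid = np.array([150.0, 200.0])
        p_ss = luc_kin.alpha * tau / (luc_kin.delta_M * luc_kin.delta_P)
        trace = tx.simulate_reporter(
            path, luc_kin, tx.NoiseParams(), grid, m0=0.0, p0=0.0
        )
        np.testing.assert_allclose(trace.values, p_ss, rtol=1e-8)

    @pytest.mark.parametrize("draw", range(10))
    def test_matches_fine_grid_integrator(self, draw, calibrated):
        """Closed-form piecewise solution vs an independent ODE solver."""
        rng = np.random.default_rng(1000 + draw)
        kin = tx.KineticParams(
            delta_M=rng.uniform(0.2, 1.5),
            delta_P=rng.uniform(0.1, 1.0),
            alpha=rng.uniform(0.5, 2.0),
        )
        path = tx.sample_switch_path(calibrated, 30.0, seed=rng)
        grid = np.arange(0.5, 30.0, 0.9)
        m0, p0 = rng.uniform(0, 20), rng.uniform(0, 50)
        trace = tx.simulate_reporter(
            path, kin, tx.NoiseParams(), grid, m0=m0, p0=p0
        )

        def rhs(t, y):
            tau = float(path.rate_at(t))
            return [tau - kin.delta_M * y[0], kin.alpha * y[0] - kin.delta_P * y[1]]

        sol = solve_ivp(
            rhs, (0.0, 30.0), [m0, p0], t_eval=grid, max_step=0.001,
            rtol=1e-10, atol=1e-12,
        )
        np.testing.assert_allclose(trace.values, sol.y[1], rtol=1e-6)

    def test_noise_is_seed_deterministic(self, single_pulse_path, luc_kin, hourly_grid):
        noise = tx.NoiseParams(sd_additive=0.5, cv_multiplicative=0.05)
        a = tx.simulate_reporter(single_pulse_path, luc_kin, noise, hourly_grid, seed=9)
        b = tx.simulate_reporter(single_pulse_path, luc_kin, noise, hourly_grid, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_grid_outside_support_raises(self, single_pulse_path, luc_kin):
        with pytest.raises(DataError):
            tx.simulate_reporter(
                single_pulse_path, luc_kin, tx.NoiseParams(), np.array([0.0, 31.0])
            )


class TestDualCell:
    def test_shared_noiseless_identical_kinetics_identical_traces(self, calibrated):
        kin = tx.KineticParams(delta_M=0.7, delta_P=0.35)
        cell = tx.simulate_dual_cell(
            calibrated, kin, kin, coupling="shared", stagger=0.0,
            noise=tx.NoiseParams(), seed=2,
        )
        np.testing.assert_array_equal(cell.luc.values, cell.gfp.values)

    def test_stagger_offsets_gfp_grid(self, calibrated, luc_kin, gfp_kin):
        cell = tx.simulate_dual_cell(
            calibrated, luc_kin, gfp_kin, coupling="independent", seed=2
        )
        assert cell.gfp.times[0] - cell.luc.times[0] == pytest.approx(0.5)

    def test_stagger_must_be_below_sampling_interval(self, calibrated, luc_kin, gfp_kin):
        with pytest.raises(ParameterError):
            tx.simulate_dual_cell(
                calibrated, luc_kin, gfp_kin, dt=1.0, stagger=1.5, seed=0
            )

    def test_independent_paths_are_uncorrelated(self, calibrated, luc_kin, gfp_kin):
        from scipy.stats import spearmanr

        grid = np.arange(0.0, 21.0, 0.5)
        rhos = []
        for seed in range(50):
            cell = tx.simulate_dual_cell(
                calibrated, luc_kin, gfp_kin, coupling="independent", seed=seed
            )
            rhos.append(
                spearmanr(cell.path_luc.rate_at(grid), cell.path_gfp.rate_at(grid)).statistic
            )
        assert abs(np.nanmedian(rhos)) < 0.15


class TestPopulation:
    def test_same_seed_identical_output(self):
        a = tx.simulate_population(5, "paper-calibrated", seed=11)
        b = tx.simulate_population(5, "paper-calibrated", seed=11)
        for ca, cb in zip(a.cells, b.cells):
            np.testing.assert_array_equal(ca.luc.values, cb.luc.values)
            np.testing.assert_array_equal(ca.gfp.values, cb.gfp.values)
            np.testing.assert_array_equal(
                ca.path_luc.switch_times, cb.path_luc.switch_times
            )

    def test_calibrated_preset_obeys_refractory(self, small_population):
        for cell in small_population.cells:
            for s, e, state in cell.path_luc.intervals()[1:-1]:
                if state == "off":
                    assert e - s >= 3.0

    def test_unknown_scenario_raises(self):
        with pytest.raises(ParameterError):
            tx.simulate_population(3, "no-such-scenario", seed=0)


class TestDecayExperiment:
    def test_translation_block_log_linear(self, luc_kin):
        grid = np.linspace(0.0, 8.0, 17)
        trace = tx.simulate_decay_experiment(
            "translation-block", luc_kin, m0=4.0, p0=20.0, grid=grid
        )
        slope = np.polyfit(grid, np.log(trace.values), 1)[0]
        assert slope == pytest.approx(-luc_kin.delta_P, rel=1e-10)

    def test_transcription_block_equal_rates_vs_integrator(self):
        kin = tx.KineticParams(delta_M=0.4, delta_P=0.4)
        grid = np.linspace(0.0, 10.0, 21)
        trace = tx.simulate_decay_experiment(
            "transcription-block", kin, m0=6.0, p0=10.0, grid=grid
        )

        def rhs(t, y):
            return [-kin.delta_M * y[0], kin.alpha * y[0] - kin.delta_P * y[1]]

        sol = solve_ivp(rhs, (0, 10), [6.0, 10.0], t_eval=grid, rtol=1e-11, atol=1e-13)
        np.testing.assert_allclose(trace.values, sol.y[1], rtol=1e-6)

    def test_transcription_block_decays_to_zero_after_single_maximum(self, luc_kin):
        grid = np.linspace(0.0, 60.0, 301)
        trace = tx.simulate_decay_experiment(
            "transcription-block", luc_kin, m0=10.0, p0=1.0, grid=grid
        )
        peak = np.argmax(trace.values)
        assert np.all(np.diff(trace.values[peak:]) <= 0)
        assert trace.values[-1] < 1e-3 * trace.values[peak]
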