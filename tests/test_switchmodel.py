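"""Binary switch-model MCMC: recovery, invariants, duration extraction."""

import numpy as np
import pytest

import txcycle as tx
from txcycle.datatypes import DataError, DurationSet
from txcycle.switchmodel import (
    SwitchModelConfig,
    SwitchPosterior,
    duration_association,
    extract_durations,
    remove_weak_switches,
    run_switch_mcmc,
)

FAST = SwitchModelConfig(iterations=6000, burn_in=2000, thin=4, seed=77)


@pytest.fixture(scope="module")
def pulse_posterior(request):
    path = tx.SwitchPath(np.array([8.0, 12.0]), "off", (0.0, 10.0), 30.0)
    grid = np.arange(0.0, 30.0 + 1e-9, 1.0)
    noise = tx.NoiseParams(sd_additive=0.05, cv_multiplicative=0.01)  # near-noiseless
    trace = tx.simulate_reporter(
        path, tx.LUC_KINETICS, noise, grid, seed=5, m0=0.0, p0=0.0
    )
    return run_switch_mcmc(trace, tx.LUC_KINETICS, FAST)


class TestRecovery:
    def test_single_pulse_mode_and_tight_times(self, pulse_posterior):
        post = pulse_posterior
        assert post.modal_k() == 2
        mat, z0 = post.switch_time_matrix()
        assert z0 == "off"
        assert mat.std(axis=0).max() < 0.25
        np.testing.assert_allclose(mat.mean(axis=0), [8.0, 12.0], atol=0.5)

    def test_levels_recovered(self, pulse_posterior):
        assert np.mean(pulse_posterior.beta_on) == pytest.approx(10.0, rel=0.1)
        assert np.mean(pulse_posterior.beta_off) == pytest.approx(0.0, abs=0.5)

    def test_steady_trace_prefers_no_switches(self):
        grid = np.arange(0.0, 30.0 + 1e-9, 1.0)
        path = tx.SwitchPath(np.empty(0), "on", (0.0, 5.0), 30.0)
        trace = tx.simulate_reporter(
            path, tx.LUC_KINETICS,
            tx.NoiseParams(sd_additive=0.05, cv_multiplicative=0.01),
            grid, seed=6,
            m0=5.0 / tx.LUC_KINETICS.delta_M,
            p0=5.0 / (tx.LUC_KINETICS.delta_M * tx.LUC_KINETICS.delta_P),
        )
        post = remove_weak_switches(run_switch_mcmc(trace, tx.LUC_KINETICS, FAST))
        assert post.modal_k() == 0

    def test_posterior_intervals_cover_truth(self, small_population):
        """95% marginal intervals on switch times cover most true switches."""
        covered = total = 0
        for i, cell in enumerate(small_population.cells):
            cfg = SwitchModelConfig(iterations=8000, burn_in=3000, thin=5, seed=100 + i)
            post = remove_weak_switches(run_switch_mcmc(cell.luc, tx.LUC_KINETICS, cfg))
            mat, _ = post.switch_time_matrix()
            if mat.size == 0:
                continue
            lo = np.quantile(mat, 0.025, axis=0) - 0.25  # half a sampling interval
            hi = np.quantile(mat, 0.975, axis=0) + 0.25
            truth = cell.path_luc.switch_times
            for a, b in zip(lo, hi):
                total += 1
                if np.any((truth >= a) & (truth <= b)):
                    covered += 1
        assert total >= 10
        assert covered / total >= 0.75

    def test_same_seed_gives_identical_chain(self):
        grid = np.arange(0.0, 30.0 + 1e-9, 1.0)
        path = tx.SwitchPath(np.array([10.0, 14.0]), "off", (0.0, 8.0), 30.0)
        noise = tx.default_noise(tx.CALIBRATED_SWITCH, tx.LUC_KINETICS)
        trace = tx.simulate_reporter(path, tx.LUC_KINETICS, noise, grid, seed=2)
        cfg = SwitchModelConfig(iterations=3000, burn_in=1000, thin=4, seed=9)
        a = run_switch_mcmc(trace, tx.LUC_KINETICS, cfg)
        b = run_switch_mcmc(trace, tx.LUC_KINETICS, cfg)
        np.testing.assert_array_equal(a.k, b.k)
        np.testing.assert_array_equal(a.beta_on, b.beta_on)
        for ta, tb in zip(a.switch_times, b.switch_times):
            np.testing.assert_array_equal(ta, tb)

    def test_every_sample_is_ordered(self, pulse_posterior):
        for t in pulse_posterior.switch_times:
            assert np.all(np.diff(t) > 0)
        assert np.all(pulse_posterior.beta_on > pulse_posterior.beta_off)


def _constructed_posterior(times, z0, n=50, record=20.0):
    return SwitchPosterior(
        cell_id="c",
        record_length=record,
        kin=tx.LUC_KINETICS,
        k=np.full(n, len(times), dtype=int),
        switch_times=[np.array(times, dtype=float)] * n,
        initial_state=[z0] * n,
        beta_off=np.zeros(n),
        beta_on=np.full(n, 10.0),
        sigma=np.full(n, 0.1),
        cv=np.full(n, 0.05),
        m0=np.ones(n),
        p0=np.ones(n),
        loglik=np.zeros(n),
    )


class TestDurations:
    def test_constructed_path_arithmetic(self):
        # switches {2, 6, 13, 17} starting off: on-phases 2-6 and 13-17,
        # complete off-phase 6-13, on-to-on period 13-2 = 11
        post = _constructed_posterior([2.0, 6.0, 13.0, 17.0], "off")
        ds = extract_durations(post)
        assert set(ds.on_durations) == {4.0}
        np.testing.assert_array_equal(ds.off_durations, [7.0])
        np.testing.assert_array_equal(ds.periods, [11.0])
        assert ds.first_interior_state == "on"

    def test_too_few_switches_gives_empty_set(self):
        post = _constructed_posterior([5.0], "off")
        ds = extract_durations(post)
        assert ds.on_durations.size == 0 and ds.off_durations.size == 0

    def test_map_estimator_accepted(self):
        post = _constructed_posterior([2.0, 6.0, 13.0, 17.0], "off")
        ds = extract_durations(post, estimator="MAP")
        np.testing.assert_array_equal(ds.off_durations, [7.0])
        with pytest.raises(DataError):
            extract_durations(post, estimator="bogus")


class TestWeakSwitches:
    def test_no_weak_switches_is_identity(self):
        post = _constructed_posterior([2.0, 6.0, 13.0, 17.0], "off")
        out = remove_weak_switches(post, threshold=0.2)
        for a, b in zip(out.switch_times, post.switch_times):
            np.testing.assert_array_equal(a, b)

    def test_brief_blip_removed(self):
        post = _constructed_posterior([2.0, 6.0, 9.0, 9.1, 13.0, 17.0], "off")
        out = remove_weak_switches(post, threshold=0.2)
        assert out.modal_k() == 4
        np.testing.assert_allclose(out.switch_times[0], [2.0, 6.0, 13.0, 17.0])

    def test_zero_threshold_is_identity(self):
        post = _constructed_posterior([2.0, 2.01, 6.0, 13.0], "off")
        out = remove_weak_switches(post, threshold=0.0)
        assert out is post


class TestAssociation:
    def test_perfectly_coupled_durations(self):
        on = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ds = DurationSet(on_durations=on, off_durations=2 * on,
                         first_interior_state="on")
        res = duration_association(ds, n_perm=200, seed=0)
        assert res["rho"] == pytest.approx(1.0)

    def test_anti_coupled_durations(self):
        on = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ds = DurationSet(on_durations=on, off_durations=10 - on,
                         first_interior_state="on")
        res = duration_association(ds, n_perm=200, seed=0)
        assert res["rho"] == pytest.approx(-1.0)

    def test_independent_durations_not_significant(self, rng):
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            sets = [
                DurationSet(
                    on_durations=rng.exponential(4.0, 5),
                    off_durations=3 + rng.exponential(3.5, 5),
                    first_interior_state="on",
                )
                for _ in range(20)
            ]
            res = duration_association(sets, n_perm=200, seed=int(rng.integers(2**31)))
            if abs(res["rho"]) < 0.2 and res["p_value"] > 0.05:
                hits += 1
        assert hits / n_rep >= 0.8
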