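"""Off-time statistics: exponential fits, memory function, cyclicity."""

import numpy as np
import pytest

from txcycle.datatypes import DataError
from txcycle.refractory import (
    cyclicity_simulation,
    empirical_sampler,
    exponential_ks_test,
    fit_exponential_same_mean,
    histogram_mode,
    memory_function,
    shift_by_refractory,
)


class TestExponentialFit:
    def test_rate_is_reciprocal_mean(self):
        fit = fit_exponential_same_mean(np.full(20, 2.0), grid=np.array([0.0, 1.0]))
        assert fit["rate"] == pytest.approx(0.5)
        assert fit["density"][0] == pytest.approx(0.5)

    def test_nonpositive_rejected(self):
        with pytest.raises(DataError):
            fit_exponential_same_mean(np.array([1.0] * 9 + [-1.0]))


class TestKsTest:
    def test_exponential_sample_usually_accepted(self, rng):
        accepted = sum(
            exponential_ks_test(rng.exponential(4.0, 300), n_boot=200, seed=i)["p_value"]
            >= 0.05
            for i in range(30)
        )
        assert accepted / 30 >= 0.85

    def test_refractory_sample_rejected(self, rng):
        rejected = sum(
            exponential_ks_test(
                3.0 + rng.exponential(3.5, 200), n_boot=200, seed=i
            )["p_value"] < 0.05
            for i in range(20)
        )
        assert rejected / 20 >= 0.95


class TestMemoryFunction:
    def test_prob_at_zero_wait_is_one(self, rng):
        mc = memory_function(rng.exponential(4.0, 500))
        np.testing.assert_array_equal(mc.prob[:, 0], 1.0)

    def test_prob_non_increasing_in_t(self, rng):
        mc = memory_function(3.0 + rng.exponential(3.5, 1000))
        assert np.all(np.diff(mc.prob, axis=1) <= 1e-12)

    def test_exponential_data_is_memoryless(self, rng):
        d = rng.exponential(4.0, 2000)
        mc = memory_function(d)
        # flat in s: within 3 Monte-Carlo standard errors of exp(-t/mean)
        for i in range(mc.s_grid.size):
            se = np.sqrt(
                mc.exponential_reference * (1 - mc.exponential_reference)
                / mc.n_survivors[i]
            )
            dev = np.abs(mc.prob[i] - mc.exponential_reference)
            assert np.all(dev <= 3 * se + 1e-12)

    def test_refractory_bound_is_exact(self, rng):
        d = 3.0 + rng.exponential(3.5, 1000)
        mc = memory_function(d)
        for i, s in enumerate(mc.s_grid):
            if s < 3.0:
                j = np.searchsorted(mc.t_values, 3.0 - s)
                assert mc.prob[i, j] == pytest.approx(1.0)

    def test_two_point_distribution_matches_enumeration(self):
        # durations 2 (x60) and 5 (x40): P(D > s+t | D > s) enumerable
        d = np.concatenate([np.full(60, 2.0), np.full(40, 5.0)])
        mc = memory_function(d, s_grid=np.array([0.0, 1.0, 3.0]), t_max=3.0)
        # s = 0: survivors all 100; P(D > 2.5) = 40/100
        i0 = np.where(mc.s_grid == 0.0)[0][0]
        j = np.where(mc.t_values == 2.5)[0][0]
        assert mc.prob[i0, j] == pytest.approx(0.40)
        # s = 3: survivors are the 40 fives; P(D > 4.5 | D > 3) = 1
        i3 = np.where(mc.s_grid == 3.0)[0][0]
        j15 = np.where(mc.t_values == 1.5)[0][0]
        assert mc.prob[i3, j15] == pytest.approx(1.0)


class TestRefractoryShift:
    def test_remove_then_enforce_is_identity(self, rng):
        d = 3.0 + rng.exponential(3.5, 200)
        out = shift_by_refractory(
            shift_by_refractory(d, 3.0, "remove"), 3.0, "enforce"
        )
        np.testing.assert_allclose(out, d)

    def test_remove_with_offenders_raises(self):
        with pytest.raises(DataError, match="below the refractory"):
            shift_by_refractory(np.array([2.0, 4.0, 5.0]), 3.0, "remove")

    def test_removed_excess_is_exponential(self, rng):
        d = 3.0 + rng.exponential(3.5, 500)
        excess = shift_by_refractory(d, 3.0, "remove")
        res = exponential_ks_test(excess[excess > 0], n_boot=300, seed=0)
        assert res["p_value"] >= 0.05


def test_histogram_mode_left_edge():
    d = np.array([3.1, 3.2, 3.4, 3.9, 4.6, 5.1])
    assert histogram_mode(d) == pytest.approx(3.0)


class TestCyclicity:
    def test_deterministic_durations_give_zero_variance(self):
        on = lambda rng, size: np.full(size, 4.0)
        off = lambda rng, size: np.full(size, 7.0)
        res = cyclicity_simulation(on, off, n_cells=40, seed=0)
        assert res.fraction_detected > 0.9
        assert res.variance < 0.5
        assert np.mean(res.first_peak_times) == pytest.approx(11.0, abs=1.0)

    def test_refractory_reduces_first_peak_variance(self):
        on = lambda rng, size: rng.exponential(4.0, size)
        off_refr = lambda rng, size: 3.0 + rng.exponential(3.5, size)
        off_tele = lambda rng, size: rng.exponential(6.5, size)
        wins = 0
        for rep in range(5):
            a = cyclicity_simulation(on, off_refr, n_cells=600, seed=900 + rep)
            b = cyclicity_simulation(on, off_tele, n_cells=600, seed=900 + rep)
            wins += b.variance > a.variance
        assert wins >= 4

    def test_monte_carlo_se_shrinks_with_population_size(self):
        on = lambda rng, size: rng.exponential(4.0, size)
        off = lambda rng, size: 3.0 + rng.exponential(3.5, size)
        small = [
            cyclicity_simulation(on, off, n_cells=100, seed=10 + i).variance
            for i in range(8)
        ]
        large = [
            cyclicity_simulation(on, off, n_cells=400, seed=50 + i).variance
            for i in range(8)
        ]
        assert np.std(large) < np.std(small)

    def test_empirical_sampler_resamples_input(self, rng):
        d = np.array([1.0, 2.0, 3.0])
        sampler = empirical_sampler(d)
        draws = sampler(rng, 100)
        assert set(np.unique(draws)).issubset(set(d))
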