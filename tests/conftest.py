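import numpy as np
import pytest

import txcycle as tx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def calibrated():
    return tx.CALIBRATED_SWITCH


@pytest.fixture
def luc_kin():
    return tx.LUC_KINETICS


@pytest.fixture
def gfp_kin():
    return tx.GFP_KINETICS


@pytest.fixture
def single_pulse_path():
    """A single 4-h on-pulse on a 30-h record, off elsewhere."""
    return tx.SwitchPath(
        switch_times=np.array([8.0, 12.0]),
        initial_state="off",
        levels=(0.0, 10.0),
        duration=30.0,
    )


@pytest.fixture
def hourly_grid():
    return np.arange(0.0, 30.0 + 1e-9, 1.0)


@pytest.fixture(scope="session")
def small_population():
    """Six calibrated dual-reporter cells shared across tests."""
    return tx.simulate_population(6, "paper-calibrated", seed=42)
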