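import numpy as np
import pytest

import reefsbi as rb


@pytest.fixture(scope="session")
def grid():
    return rb.make_wavelength_grid(400, 700, 5)


@pytest.fixture(scope="session")
def simulator(grid):
    return rb.ShallowWaterSimulator(grid)


@pytest.fixture(scope="session")
def priors():
    return rb.default_priors()


@pytest.fixture(scope="session")
def typical_theta():
    return rb.ParameterVector(
        phytoplankton=0.3, cdom440=0.05, minerals=0.5, wind=6.0, depth=5.0
    )


@pytest.fixture(scope="session")
def small_campaign(priors, simulator):
    """A modest noise-free campaign reused across tests."""
    return rb.run_campaign(priors, simulator, 3000, seed=42)


@pytest.fixture(scope="session")
def trained_bundle():
    """A compact trained pipeline shared by estimator/diagnostics tests.

    Small but real: 6,000 simulations at SNR 100 with a reduced epoch
    budget keep the suite fast while exercising the full training path.
    """
    cfg = rb.MDNConfig(max_epochs=150)
    return rb.run_pipeline(
        n_simulations=6000, n_test=300, snr=100.0, seed=7, mdn_config=cfg
    )
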