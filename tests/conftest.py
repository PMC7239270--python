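import numpy as np
import pytest

from cutipart import LeafSeries, SimulationParams, simulate_experiment


@pytest.fixture()
def simple_leaf() -> LeafSeries:
    """One control leaf with a perfectly linear drying curve."""
    times = np.arange(0.0, 7.0)
    weights = 1.000 - 0.0075 * times  # 0.30 mg h-1 cm-2 at A = 25
    return LeafSeries(
        leaf_id="L1",
        treatment="CONTROL",
        area=25.0,
        w_initial=1.000,
        w_dry=0.400,
        times=times,
        weights=weights,
    )


@pytest.fixture(scope="session")
def ideal_params() -> SimulationParams:
    """Noise-free generator with stomata fully shut: exact inversion territory."""
    return SimulationParams(g_s0=0.0, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def ideal_experiment(ideal_params):
    return simulate_experiment(ideal_params)


@pytest.fixture(scope="session")
def default_experiment():
    return simulate_experiment(SimulationParams(seed=11))
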