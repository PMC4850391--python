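import numpy as np
import pytest

from percosc import ExperimentConfig, default_observer, simulate_experiment


@pytest.fixture(scope="session")
def config():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def observer(config):
    return default_observer(config)


@pytest.fixture(scope="session")
def small_datasets(config, observer):
    """Three modulated observers at desk scale; shared across tests."""
    return simulate_experiment(config, observer, 3, 33, np.random.default_rng(11))


@pytest.fixture(scope="session")
def null_datasets(config, observer):
    """Two observers with zero phase modulation."""
    return simulate_experiment(
        config, observer.with_zero_modulation(), 2, 33, np.random.default_rng(12)
    )
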