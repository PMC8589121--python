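import numpy as np
import pytest

from stdptail.encoding import generate_synthetic_patterns
from stdptail.lif import NeuronParams, build_network
from stdptail.stdp import STDPConfig


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 3-class pattern set shared across tests."""
    return generate_synthetic_patterns(
        n_classes=3, image_size=(8, 8), samples_per_class=40, seed=7
    )


@pytest.fixture(scope="session")
def exc_params():
    return NeuronParams.excitatory(tau_theta=1e4, theta_inc=0.5)


@pytest.fixture(scope="session")
def inh_params():
    return NeuronParams.inhibitory()


@pytest.fixture()
def tiny_topology():
    return build_network(64, 16, init_seed=3)


@pytest.fixture()
def log_cfg():
    return STDPConfig.for_rule("log", eta=0.05, W0=0.5, sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
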