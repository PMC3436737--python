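import numpy as np
import pytest

from tcellfate import InfluenceNetwork, get_model


@pytest.fixture(scope="session")
def generic1():
    return get_model("generic1").network


@pytest.fixture(scope="session")
def generic3_factory():
    def make(auto_weight=1.5):
        return get_model("generic3", auto_weight=auto_weight).network

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_two_node(rng, auto_scale=2.0):
    """A random well-posed 2-node mutual-inhibition-style network."""
    omega = rng.uniform(-3.0, auto_scale, size=(2, 2))
    return InfluenceNetwork(
        node_names=("X", "Y"),
        signal_names=("S1", "S2", "S3"),
        omega=omega,
        omega0=rng.uniform(-2.0, 0.5, size=2),
        signal_omega=rng.uniform(0.0, 1.0, size=(3, 2)),
        sigma=rng.uniform(1.0, 4.0, size=2),
        gamma=rng.uniform(1.0, 6.0, size=2),
    )


@pytest.fixture
def one_node_factory():
    def make(omega0=-1.0, auto=0.0, sigma=2.0, gamma=1.0, s_weight=1.0):
        return InfluenceNetwork(
            node_names=("X",),
            signal_names=("S",),
            omega=[[auto]],
            omega0=[omega0],
            signal_omega=[[s_weight]],
            sigma=sigma,
            gamma=gamma,
            regulator_pair=None,
        )

    return make
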