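import numpy as np
import pytest

from avcausal.experiments import NetworkModel, make_model
from avcausal.network import ConnectivityParams, build_connectivity, build_geometry


@pytest.fixture(scope="session")
def geom():
    """Default 1000-neuron geometry on [-50, 50] deg."""
    return build_geometry()


@pytest.fixture(scope="session")
def weights(geom):
    """Default Mexican-hat weight matrix (built once per session)."""
    return build_connectivity(geom, ConnectivityParams())


@pytest.fixture(scope="session")
def linear_model():
    """Default threshold-linear network model with cached weights."""
    return make_model("network-linear")


@pytest.fixture(scope="session")
def squared_model():
    return make_model("network-squared")


@pytest.fixture(scope="session")
def small_geom():
    """Coarse 64-neuron strip for fast property tests."""
    return build_geometry(n=64, angle_min=-50.0, angle_max=50.0)


@pytest.fixture(scope="session")
def small_weights(small_geom):
    return build_connectivity(small_geom, ConnectivityParams())


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
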