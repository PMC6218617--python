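import numpy as np
import pytest

from mumse.io import Recording
from mumse.network import ConnectivityGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """4-channel, 2 s noise recording at 250 Hz."""
    data = rng.standard_normal((4, 500)) * 10.0
    return Recording(data, 250.0, ("C3", "C4", "Cz", "O1"))


@pytest.fixture
def uniform_graph():
    """Complete 6-node graph, every weight 1."""
    W = np.ones((6, 6)) - np.eye(6)
    labels = tuple(f"n{i}" for i in range(6))
    return ConnectivityGraph(labels, W)
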