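import numpy as np
import pytest

import thi


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo_complex():
    """Small seven-node simplicial complex used across tests."""
    return thi.presets.seven_node_complex()


@pytest.fixture(scope="session")
def kuramoto7_scenario():
    """Saturated noiseless Kuramoto benchmark (150 exact-derivative samples)."""
    return thi.build_preset("kuramoto7", seed=7)
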