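import numpy as np
import pytest

from emghybrid.config import NetworkConfig, SignalConfig


@pytest.fixture
def signal_cfg() -> SignalConfig:
    return SignalConfig()


@pytest.fixture
def small_net_cfg() -> NetworkConfig:
    """Two-class, two-channel network small enough for oracle checks."""
    return NetworkConfig(n_classes=2, n_states=2, n_components=2,
                         seq_len=10, input_dim=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
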