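import numpy as np
import pytest
from hypothesis import settings

from headfsi.cora import CoraConfig

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")
from headfsi.signals import SignalCurve
from headfsi.synthetic import PulseSpec, make_pulse


@pytest.fixture
def haversine_ref() -> SignalCurve:
    """Unit haversine pulse, 10 ms wide on a 0.1 ms grid (101 samples)."""
    return make_pulse(PulseSpec("haversine", 1.0, 0.01), 1e-4,
                      channel_label="reference")


@pytest.fixture
def cora_config() -> CoraConfig:
    return CoraConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_pair(rng, n=50, dt=0.01):
    """A random, non-degenerate aligned signal pair on a shared grid."""
    t = dt * np.arange(n)
    ref = rng.normal(size=n)
    test = rng.normal(size=n)
    return SignalCurve(t, ref), SignalCurve(t, test)
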