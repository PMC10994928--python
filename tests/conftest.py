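import numpy as np
import pytest

from meapipe.bursts import BurstConfig
from meapipe.core import SpikeTrain
from meapipe.spikes import DetectionConfig


@pytest.fixture
def burst_cfg():
    return BurstConfig()


@pytest.fixture
def det_cfg():
    return DetectionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def regular_train(n, isi, t0=1.0, duration=600.0, eid="e00"):
    """n spikes at a fixed inter-spike interval."""
    return SpikeTrain(t0 + np.arange(n) * isi, duration, eid)
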