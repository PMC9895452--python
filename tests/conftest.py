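import numpy as np
import pytest

from marmoephys.core import AnalysisConfig, ChannelInfo, RecordingBlock
from marmoephys.synth import make_fixture_fig8_session


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def fig8_session():
    return make_fixture_fig8_session()


@pytest.fixture
def small_block():
    """Two-channel, 100-sample block on one shank."""
    rng = np.random.default_rng(0)
    samples = rng.normal(0.0, 10.0, size=(2, 100))
    cmap = [ChannelInfo(0, 0, 0.0), ChannelInfo(0, 1, 25.0)]
    return RecordingBlock(samples, 25000.0, cmap)


def make_block(samples, rate=25000.0, n_shanks=1):
    n_ch = samples.shape[0]
    per = n_ch // n_shanks
    cmap = [
        ChannelInfo(i // per, i % per, (i % per) * 25.0) for i in range(n_ch)
    ]
    return RecordingBlock(samples, rate, cmap)
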