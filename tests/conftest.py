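import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest

import flowssvep as fs


@pytest.fixture(scope="session")
def default_spec():
    return fs.StimulusSpec()


@pytest.fixture(scope="session")
def channel_map():
    return fs.hydrocel_like_layout()


@pytest.fixture(scope="session")
def demo_topo(channel_map):
    return fs.demo_topography(channel_map)


@pytest.fixture(scope="session")
def null_topography():
    """Topography with no planted responses (pure noise)."""
    empty = pd.DataFrame(
        columns=["channel", "harmonic", "pattern", "speed", "re", "im"]
    )
    return fs.ResponseTopography(responses=empty)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
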