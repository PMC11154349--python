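import numpy as np
import pytest

from dtgcn import nn
from dtgcn.eeg import build_dist_graph
from dtgcn.synthetic import standard_1020_layout


@pytest.fixture(scope="session")
def layout():
    return standard_1020_layout()


@pytest.fixture(scope="session")
def dist_graph(layout):
    return build_dist_graph(layout, kappa=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def float32_engine():
    """Run training-scale tests in float32; always restore float64."""
    nn.set_default_dtype(np.float32)
    yield
    nn.set_default_dtype(np.float64)
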