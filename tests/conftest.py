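import numpy as np
import pytest

from snapdyn.drift import ArchConfig, DriftModel
from snapdyn.synthetic import SyntheticConfig, simulate_interacting_ou


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_arch():
    # tiny widths keep unit tests fast; contracts do not depend on width
    return ArchConfig(d=3, intra_hidden=16, d_ff=16, dropout=0.0)


@pytest.fixture
def small_model(small_arch):
    return DriftModel.initialize(small_arch, sigma=0.1, seed=7,
                                 zero_final=False)


@pytest.fixture(scope="session")
def ou_series():
    """Small mean-attraction snapshot series with its moment oracle."""
    cfg = SyntheticConfig(d=2, n_cells=300, times=(0, 1, 2, 3), seed=11)
    return simulate_interacting_ou(cfg)
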