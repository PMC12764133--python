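import numpy as np
import pytest

from pantx import synthio


@pytest.fixture(scope="session")
def small_pop():
    """A compact fully-simulated population shared by read-only tests."""
    cfg = synthio.SimConfig(
        n_lines=30, n_core=20, n_shell=40, n_cloud=15, seed=11,
        rate_shape=0.8, rate_rate=0.8 / 0.02, seq_len_range=(300, 600),
    )
    return synthio.simulate_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
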