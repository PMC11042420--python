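import numpy as np
import pytest

from organfield import synthetic_data as sd


@pytest.fixture(scope="session")
def sig_matrix():
    return sd.cosmic_like_signature_matrix()


@pytest.fixture(scope="session")
def small_organ():
    """100 alpha / 10 beta / 5 gamma organ; seed verified for exact recovery."""
    config = sd.SimOrganConfig(n_alpha=100, n_beta=10, n_gamma=5)
    return sd.simulate_whole_organ(config, seed=2)


@pytest.fixture(scope="session")
def default_organ():
    """Generator defaults: 38 fields, 1000/50/30 mutations, seed 7."""
    return sd.simulate_whole_organ(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
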