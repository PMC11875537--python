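import numpy as np
import pytest

import mgecomm as mg


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def lv_symmetric():
    """Symmetric two-species LV: mu = 0.5, gamma = 1.1, D = 0.2 (bistable)."""
    return mg.two_species(0.5, 0.5, gamma=1.1, eta=0.0, variant="classic_lv")


@pytest.fixture
def five_species():
    return mg.demo_five_species(eta=0.0)


def random_growth_state(m, rng, full_carriage=False):
    """Random valid CommunityState for growth-effect variants."""
    s = rng.uniform(0.05, 1.0, m)
    if full_carriage:
        p = np.tile(s[:, None], (1, m)).T.copy()
        p = np.repeat(s[:, None], m, axis=1)
    else:
        p = rng.uniform(0.0, 1.0, (m, m)) * s[:, None]
    np.fill_diagonal(p, s)
    return mg.CommunityState(s, p)
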