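import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_synthetic():
    """A short trajectory with bonds on both sides of the cutoff."""
    from hbstab.synthetic import SyntheticConfig, generate_trajectory

    config = SyntheticConfig(n_bonds=6, n_ticks=200, seed=11,
                             mu=np.linspace(1.8, 3.2, 6))
    return generate_trajectory(config)
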