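import numpy as np
import pytest

from blupcg import Pedigree, SimConfig, simulate_pedigree


@pytest.fixture
def trio():
    """Two unrelated founders and their offspring."""
    return Pedigree(sire=np.array([-1, -1, 0]), dam=np.array([-1, -1, 1]))


@pytest.fixture
def rng():
    return np.random.default_rng(20180814)


def random_pedigree(rng, n_founders=None, generations=None, offspring=None) -> Pedigree:
    """Small random pedigree; tight founder pools generate inbred loops."""
    cfg = SimConfig(
        n_founders=n_founders or int(rng.integers(2, 8)),
        n_generations=generations or int(rng.integers(2, 5)),
        offspring_per_generation=offspring or int(rng.integers(3, 12)),
    )
    return simulate_pedigree(cfg, rng)
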