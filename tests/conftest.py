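import numpy as np
import pytest

from timeavg.adaptive import PosteriorGrid
from timeavg.models import SET1, SET2, SET3


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sets():
    return (SET1, SET2, SET3)


@pytest.fixture(scope="session")
def coarse_grid():
    """Smaller posterior grid for simulation-heavy tests (same spans)."""
    return PosteriorGrid.default(n_alpha=31, n_beta=21, n_lam=5)
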