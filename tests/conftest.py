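import numpy as np
import pytest

from collective_guidance.dynamics import init_hexagonal_cluster


@pytest.fixture
def rng():
    return np.random.default_rng(20160701)


@pytest.fixture
def hex7():
    """Closed-shell 7-cell hexagon at unit spacing, unrotated."""
    return init_hexagonal_cluster(7, rotate=False)


@pytest.fixture
def hex19():
    return init_hexagonal_cluster(19, rotate=False)
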