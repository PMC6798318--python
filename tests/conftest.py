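import numpy as np
import pytest

from fitscape.gpmap import STEP, Environment, TraitModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model():
    """One step-sigmoid trait over three genes: w = (1, 1, -1), h = 0.5."""
    return TraitModel([[1.0, 1.0, -1.0]], [0.5], STEP)


@pytest.fixture
def two_trait_model():
    """Two smooth traits over four genes with disjoint regulation sets."""
    w = np.array([[1.0, -2.0, 0.0, 0.0], [0.0, 0.0, 1.5, 0.5]])
    return TraitModel(w, [0.0, 0.25], 2.0)


@pytest.fixture
def env2():
    return Environment([1.0, -1.0], K_F=2.0)
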