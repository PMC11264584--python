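import numpy as np
import pytest

from socialoperant.chamber import default_landmarks
from socialoperant.simulate import TrueSubjectParams


@pytest.fixture
def baseline_params() -> TrueSubjectParams:
    """A subject at the generator's baseline demand parameters."""
    return TrueSubjectParams("s0", q0_true=20.0, alpha_true=3e-3)


@pytest.fixture
def landmarks():
    return default_landmarks()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
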