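import numpy as np
import pytest
from hypothesis import settings

from memsorb.structio import CGProtein

settings.register_profile("default", derandomize=True, max_examples=25)
settings.load_profile("default")


def make_single_bead(charge: float = 1.0, epsilon: float = 0.5,
                     sigma: float = 0.5) -> CGProtein:
    """One-bead molecule; the simplest adsorbate with an analytic
    height distribution."""
    return CGProtein([[0.0, 0.0, 0.0]], [charge], [0.0], [sigma], [epsilon],
                     ["LYS" if charge > 0 else "GLY"], [1], ["A"])


@pytest.fixture
def single_bead() -> CGProtein:
    return make_single_bead()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
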