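import numpy as np
import pytest

from phaselock import AngleSample, VonMisesParams, vonmises_sample

TWO_PI = 2.0 * np.pi


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def uniform_pair():
    """Two independent uniform angle populations, n=25 each."""
    r = np.random.default_rng(11)
    return (
        AngleSample(r.uniform(0, TWO_PI, 25), label="prestim"),
        AngleSample(r.uniform(0, TWO_PI, 25), label="stim"),
    )


@pytest.fixture
def concentrated_pair():
    """Populations tightly concentrated at opposite directions."""
    return (
        vonmises_sample(VonMisesParams(0.0, 50.0), 25, seed=1),
        vonmises_sample(VonMisesParams(np.pi, 50.0), 25, seed=2),
    )
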