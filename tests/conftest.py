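import numpy as np
import pytest

from pcmaffinity._fixtures import AA_ORDER


@pytest.fixture(scope="session")
def rng():
    return np.random.RandomState(20260927)


def random_sequence(rng, length):
    return "".join(rng.choice(list(AA_ORDER), size=length))


@pytest.fixture
def seq35(rng):
    return random_sequence(rng, 35)
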