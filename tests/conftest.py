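import numpy as np
import pytest

AA = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20170808)


def random_sequence(rng, length):
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture
def random_peptides(rng):
    """100 random 16-mers, no planted structure."""
    return [random_sequence(rng, 16) for _ in range(100)]
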