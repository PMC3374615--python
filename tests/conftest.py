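import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def dna():
    """Factory for random DNA strings tied to the seeded rng."""
    local = np.random.default_rng(987654321)

    def make(n):
        return random_dna(local, n)

    return make
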