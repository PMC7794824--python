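import numpy as np
import pytest
from hypothesis import settings

from mimscout.sequence_io import CANONICAL_RESIDUES

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_sequences(rng):
    """1,000 random canonical sequences of length up to 200."""
    alphabet = np.array(list(CANONICAL_RESIDUES))
    lengths = rng.integers(0, 201, size=1000)
    return ["".join(alphabet[rng.integers(20, size=n)]) for n in lengths]
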