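import numpy as np
import pytest

from trftrace.core import Genome, random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome(rng):
    return Genome("g", random_dna(rng, 400))
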