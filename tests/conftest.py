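import numpy as np
import pytest

from iaspls.seqio import DnaSequence

from oracle_utils import random_dna


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequences(rng):
    """100 random sequences (some with ambiguity codes) for oracle suites."""
    seqs = []
    for i in range(100):
        length = int(rng.integers(60, 401))
        rate = 0.05 if i % 4 == 0 else 0.0
        seqs.append(DnaSequence(f"r{i:03d}", random_dna(rng, length, rate)))
    return seqs
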