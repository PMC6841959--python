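import numpy as np
import pytest

from idrsubmat.io import CANONICAL_ALPHABET, ProteinSequence


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def random_sequences(rng):
    """50 random canonical-alphabet sequences with distinct ids."""
    def make(n=50, min_len=20, max_len=120):
        seqs = []
        for i in range(n):
            length = int(rng.integers(min_len, max_len + 1))
            residues = "".join(
                rng.choice(list(CANONICAL_ALPHABET), size=length)
            )
            seqs.append(ProteinSequence(id=f"seq{i:03d}", residues=residues))
        return seqs

    return make
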