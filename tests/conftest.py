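import numpy as np
import pytest

BASES = "ACGT"
FLIP = {"A": "C", "C": "G", "G": "T", "T": "A"}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def mutate(seq: str, positions) -> str:
    chars = list(seq)
    for p in positions:
        chars[p] = FLIP[chars[p]]
    return "".join(chars)


@pytest.fixture
def make_seq(rng):
    def _make(n):
        return random_seq(rng, n)

    return _make
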