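import random

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGU") for _ in range(n))


@pytest.fixture
def random_sequences():
    """Deterministic batch of short random RNA sequences."""
    r = random.Random(20240917)
    return [random_rna(r, r.randint(6, 18)) for _ in range(60)]
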