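import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20241101)


def random_sequence(rng, length, with_n=False):
    bases = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(bases), size=length, p=probs))
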