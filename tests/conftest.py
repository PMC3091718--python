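import numpy as np
import pytest

from microsat.simulate import build_fixture


@pytest.fixture(scope="session")
def study():
    """One deterministic paired-genotype synthetic study shared by tests."""
    return build_fixture(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_917)


def random_dna(rng, n, gc=0.4, with_n=0.0):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=n, p=p)
    if with_n:
        mask = rng.random(n) < with_n
        seq[mask] = "N"
    return "".join(seq)
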