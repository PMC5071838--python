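import numpy as np
import pytest

from savmir import synthio


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_bundle():
    """A 12-miRNA reference bundle shared across read-only tests."""
    return synthio.make_reference(seed=7, n_mirnas=12, genome_length=20_000)


def random_seq(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
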