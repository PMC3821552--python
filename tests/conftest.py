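import numpy as np
import pytest

from onegap.scoring import load_matrix


@pytest.fixture(scope="session")
def ednafull():
    return load_matrix("EDNAFULL")


@pytest.fixture(scope="session")
def eblosum62():
    return load_matrix("EBLOSUM62")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


# the worked instances used throughout: (t, x, k, alpha, beta)
EXAMPLE_SHORT = ("AGGTCAT", "GGGTA", 1, 1, 1)
EXAMPLE_LONG = ("AGCAGAGGAGCAGGCGTTCCGTGGT", "ACCGT", 2, 6, 7)


@pytest.fixture(scope="session")
def example_short():
    return EXAMPLE_SHORT


@pytest.fixture(scope="session")
def example_long():
    return EXAMPLE_LONG


def random_seq(rng, length, letters="ACGT"):
    return "".join(rng.choice(list(letters), size=length))
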