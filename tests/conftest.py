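import numpy as np
import pytest

from p53recode import ResponseElement, reference_re


@pytest.fixture
def rng():
    return np.random.default_rng(20210120)


def random_re(rng, name="rnd", alphabet="ACGT"):
    seq = "".join(rng.choice(list(alphabet), 20))
    return ResponseElement(name=name, sequence=seq)


@pytest.fixture
def p21():
    return reference_re("p21")


@pytest.fixture
def bax():
    return reference_re("BAX")
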