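import numpy as np
import pytest

from contactdiff import ContactMap, make_pair


def symmetric_map(rng: np.random.Generator, n: int = 10, bin_size: int = 2048) -> ContactMap:
    field = rng.normal(size=(n, n))
    return ContactMap(values=(field + field.T) / 2.0, bin_size=bin_size)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_map(rng):
    return symmetric_map(rng)


@pytest.fixture
def random_pair(rng):
    return make_pair(symmetric_map(rng), symmetric_map(rng))
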