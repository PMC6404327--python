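import numpy as np
import pytest

from ambicode import (
    CodeMatrix,
    partition_to_matrix,
    random_code,
    sgc_partition,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def sgc():
    return sgc_partition()


@pytest.fixture(scope="session")
def sgc_matrix(sgc):
    return partition_to_matrix(sgc)


@pytest.fixture
def random_matrix(rng):
    return random_code(rng)


@pytest.fixture
def uniform_matrix():
    return CodeMatrix(np.full((64, 21), 1 / 21))
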