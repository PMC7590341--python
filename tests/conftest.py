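import numpy as np
import pytest

from serscreen import DEFAULT_GRID, load_table2


@pytest.fixture(scope="session")
def table2():
    return load_table2()


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
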