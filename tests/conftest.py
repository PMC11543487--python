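import numpy as np
import pytest

from descreen.dataset_io import load_screening_table


@pytest.fixture(scope="session")
def table1():
    return load_screening_table("table1")


@pytest.fixture(scope="session")
def table1_frame(table1):
    return table1.to_frame()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
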