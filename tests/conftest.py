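import numpy as np
import pytest

from cinsim import load_feature_table, per_copy_fitness


@pytest.fixture(scope="session")
def table():
    return load_feature_table()


@pytest.fixture(scope="session")
def phi(table):
    return per_copy_fitness(table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
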