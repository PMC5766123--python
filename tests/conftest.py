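import pytest

from haplogeo import bretschneidera
from haplogeo.genealogy import mj_network


@pytest.fixture(scope="session")
def dataset():
    return bretschneidera.load_dataset()


@pytest.fixture(scope="session")
def matrix(dataset):
    return dataset.matrix


@pytest.fixture(scope="session")
def network(dataset):
    return mj_network(dataset.matrix, dataset.global_counts())
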