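import numpy as np
import pytest

from matphase import datasets
from matphase.extraction import HaplotypePair


@pytest.fixture(scope="session")
def b2ar_read_matrix():
    return datasets.load_b2ar_read_matrix()


@pytest.fixture(scope="session")
def b2ar_truth():
    return HaplotypePair(datasets.B2AR_HP, datasets.B2AR_HM, ambiguous=False)


@pytest.fixture(scope="session")
def b2ar_completed():
    """The ideal completed matrix of the worked example."""
    return datasets.B2AR_H.copy()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
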