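import numpy as np
import pytest

from vrdphylo import datasets


@pytest.fixture(scope="session")
def study_set():
    return datasets.load_study_set()


@pytest.fixture(scope="session")
def zmatrix():
    return datasets.load_zscores()


@pytest.fixture(scope="session")
def charmatrix():
    return datasets.load_characters()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140509)
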