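import numpy as np
import pytest

from aagalaxy import MatrixEmbedder, load_matrix, load_property_scales


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def embedder62(blosum62):
    return MatrixEmbedder(center=True).fit(blosum62)


@pytest.fixture(scope="session")
def galaxy62(embedder62):
    return embedder62.galaxy_


@pytest.fixture(scope="session")
def scales():
    return load_property_scales(normalized=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
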