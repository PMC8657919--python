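import numpy as np
import pytest

from prospr.io_formats import Alignment
from prospr.labeling import label_chain
from prospr.network import DistogramNetwork, tiny_config
from prospr.synthetic_fixtures import compact_chain, ideal_helix, random_msa


@pytest.fixture(scope="session")
def helix12():
    return ideal_helix(12)


@pytest.fixture(scope="session")
def compact40():
    return compact_chain(40, seed=1)


@pytest.fixture(scope="session")
def small_msa():
    """Depth-30 random MSA of length 16."""
    return random_msa(16, 30, mutation_rate=0.15, seed=0)


@pytest.fixture(scope="session")
def tiny_model():
    return DistogramNetwork(tiny_config(seed=0))


@pytest.fixture(scope="session")
def helix16_labels():
    # reduced sphere sampling keeps session setup fast; binning is coarse
    return label_chain(ideal_helix(16), sasa_points=120)


def make_alignment(rows, ids=None):
    return Alignment(query_id="q", sequences=list(rows), ids=ids)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
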