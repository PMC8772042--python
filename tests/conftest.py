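import numpy as np
import pytest

from recurbin.cli import DEFAULT_MODEL_PATH
from recurbin.marker_quality import MarkerSetCatalog
from recurbin.prob_model import load_model
from recurbin.synthetic_data import (
    SyntheticCommunitySpec,
    default_catalog,
    generate_community,
)


@pytest.fixture(scope="session")
def model():
    """The packaged default probability model."""
    return load_model(DEFAULT_MODEL_PATH)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def toy_catalog():
    """Two collocated sets {g1, g2} and {g3} for hand-checkable quality values."""
    return MarkerSetCatalog("toy", [["g1", "g2"], ["g3"]])


@pytest.fixture(scope="session")
def community(catalog):
    """A well-separated 10-genome, 3-sample planted community."""
    return generate_community(SyntheticCommunitySpec(rng_seed=1), catalog)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
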