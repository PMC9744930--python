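import numpy as np
import pytest

from facebench import faces
from facebench.pipeline import ExperimentConfig, prepare_assets

CANVAS = (140, 190)  # quarter-scale working canvas used throughout the suite


@pytest.fixture(scope="session")
def proto_pair():
    return faces.make_prototype_pair(seed=1, canvas_size=CANVAS)


@pytest.fixture(scope="session")
def continuum(proto_pair):
    a, b = proto_pair
    return faces.make_morph_continuum(a, b)


@pytest.fixture(scope="session")
def assets():
    """Fully trained desk-scale pipeline assets (trained once per session)."""
    return prepare_assets(ExperimentConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
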