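import numpy as np
import pytest

from spinemetrics.phantom import (
    PhantomConfig,
    generate_geometry,
    rasterize_masks,
    render_pair,
)


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig(coronal_curves=(("T9", 30.0),), seed=42)


@pytest.fixture(scope="session")
def default_geometry(default_config):
    return generate_geometry(default_config)


@pytest.fixture(scope="session")
def default_pair(default_config, default_geometry):
    return render_pair(default_geometry, default_config)


@pytest.fixture(scope="session")
def default_masks(default_config, default_geometry):
    return rasterize_masks(default_geometry, default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
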