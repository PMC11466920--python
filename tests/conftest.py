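import numpy as np
import pytest

from duoseg import ModelConfig, PhantomSpec, make_dataset
from duoseg.nn import seed_all


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(autouse=True)
def _seeded_weights():
    seed_all(0)


@pytest.fixture
def tiny_cfg():
    return ModelConfig.tiny()


@pytest.fixture(scope="session")
def phantom_spec_64():
    return PhantomSpec().scaled(64)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, phantom_spec_64):
    """10 phantoms at 64 px with a manifest, shared across tests."""
    out = tmp_path_factory.mktemp("phantoms")
    manifest = make_dataset(phantom_spec_64, 10, out, seed=3)
    return out, manifest
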