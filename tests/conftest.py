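import numpy as np
import pytest

from ltpnet import nn


@pytest.fixture(autouse=True)
def _seed_everything():
    nn.manual_seed(0)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_fmap(rng):
    def make(shape=(1, 8, 4, 4)):
        return nn.Tensor(rng.normal(size=shape))

    return make


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """8 synthetic 64x64 pairs shared across tests that need files."""
    from ltpnet.synth import SynthParams, generate_split

    root = tmp_path_factory.mktemp("tiny_data")
    params = SynthParams(image_size=(64, 64), seed=7,
                         lesion_area_fraction=(0.08, 0.30))
    generate_split(8, params, root)
    return root
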