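import numpy as np
import pytest

from dcdnet import DCDNet, DCDNetConfig, FixtureSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small on-disk synthetic dataset (8 cases at a reduced canvas)."""
    out = tmp_path_factory.mktemp("fixtures")
    spec = FixtureSpec(n_images=8, height=96, width=192,
                       lesion_size_px=(10, 20), noise_sd=4.0, seed=7)
    manifest = generate_dataset(spec, out)
    return out, manifest


@pytest.fixture(scope="session")
def small_model():
    """A compact seeded network reused by read-only tests."""
    return DCDNet(DCDNetConfig(backbone="mobilenetv2", input_h=32, input_w=64,
                               seed=11))
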