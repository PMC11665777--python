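import numpy as np
import pytest

import plutonet as p


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """Full network at 64px input — cheap enough for repeated forwards."""
    return p.PlutoNet(p.EncoderConfig(input_size=64), seed=3)


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """A small 64px phantom dataset with manifest, shared across tests."""
    out = tmp_path_factory.mktemp("phantoms64")
    spec = p.PhantomSpec(image_size=64, seed=11)
    manifest = p.generate_dataset(spec, 10, out)
    return out, manifest
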