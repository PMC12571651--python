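import numpy as np
import pytest

from clinvla.config import ModelConfig, TrainConfig
from clinvla.models import build_model
from clinvla.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """64 dual-view records (8 classes x 8), small images for speed."""
    spec = SyntheticSpec(n_classes=8, n_per_class=8, image_side=64, seed=1)
    records, manifest = generate_dataset(spec)
    labels = np.array([m["class_id"] for m in manifest])
    return records, manifest, labels


@pytest.fixture()
def tiny_model_config():
    return ModelConfig(h=32, depth=2, n_heads=2, d=8, vocab_size=512,
                       image_side=64, seed=1)


@pytest.fixture()
def tiny_model(tiny_model_config):
    return build_model(tiny_model_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
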