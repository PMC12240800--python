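import numpy as np
import pytest

from morphocloud import packing
from morphocloud.nn import ModelConfig, train


@pytest.fixture(scope="session")
def unit_sphere():
    """Watertight icosphere of radius 1 (resolution 4)."""
    return packing.make_nucleus_shape((1.0, 1.0, 1.0), 0.0, 4, seed=0)


@pytest.fixture(scope="session")
def small_nucleus():
    """Deformed anisotropic nucleus used across packing tests."""
    return packing.sample_nucleus(packing.PackingConfig(), seed=11)


@pytest.fixture(scope="session")
def tiny_trained_model():
    """Small autoencoder trained for a few epochs on random 64-point clouds."""
    rng = np.random.default_rng(0)
    clouds = [rng.normal(size=(64, 3)) for _ in range(8)]
    config = ModelConfig(
        bottleneck=16,
        hidden_channels=(8, 8, 8),
        k_neighbors=8,
        template_points=64,
        epochs=3,
        lr=2e-3,
        seed=5,
    )
    model, log = train(clouds, config)
    return model, clouds, log
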