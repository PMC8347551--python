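import numpy as np
import pytest

from facnet.synthetic import SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_synth_set():
    """40 small (32x32) synthetic samples shared by the training smoke tests."""
    cfg = SynthConfig(n_images=40, image_size=32, seed=7, contrast=0.8,
                      boundary_blur_sigma=0.8, hair_count_range=(0, 2),
                      bubble_count_range=(0, 1), noise_sigma=0.01)
    return generate(cfg)
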