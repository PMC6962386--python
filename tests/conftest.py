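import numpy as np
import pytest

from uhdog.image_io import ImageGrid
from uhdog import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def single_blob_image():
    """One noise-free Gaussian blob (radius 6) centered in a 49x49 grid."""
    n, radius = 49, 6.0
    yy, xx = np.mgrid[:n, :n].astype(float)
    c = n // 2
    data = np.exp(-((yy - c) ** 2 + (xx - c) ** 2) / (2 * (radius / 2.0) ** 2))
    return ImageGrid(data), (float(c), float(c)), radius


@pytest.fixture(scope="session")
def blob_sample():
    """Default synthetic fluorescence-style field with ground truth."""
    return synthetic.generate_blob_image(synthetic.BlobSpec(seed=42))


@pytest.fixture(scope="session")
def tiny_trained_model():
    """A small U-Net overfit briefly on a few synthetic pairs (shared)."""
    from uhdog.unet_prob import TrainConfig, make_training_pair, train

    masks = synthetic.generate_training_masks(3, dims=(32, 32), seed=5)
    pairs = [make_training_pair(m, seed=50 + i) for i, m in enumerate(masks)]
    return train(pairs, TrainConfig(depth=2, base_channels=8, steps=60), seed=5), pairs
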