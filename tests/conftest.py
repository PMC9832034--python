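import numpy as np
import pytest

from octseg.phantom import PhantomSpec, generate_bscan, sample_presence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """Miniature phantom geometry used by the fast tests."""
    return PhantomSpec(image_width=32, image_depth=32, axial_resolution=3.87 * 496 / 32)


@pytest.fixture(scope="session")
def tiny_phantom_batch(tiny_spec):
    """Eight 32x32 phantom scans with masks, shared across tests."""
    rng = np.random.default_rng(7)
    images, masks = [], []
    for _ in range(8):
        present = sample_presence(tiny_spec, rng)
        scan, mask, _ = generate_bscan(tiny_spec, present, rng)
        images.append(scan.image.astype(np.float32) / 255.0)
        masks.append(mask.astype(np.int64))
    x = np.stack(images)[:, None]
    y = np.stack(masks)
    return x, y
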