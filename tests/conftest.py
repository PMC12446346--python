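import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from stromaspatial import PhantomConfig, generate_phantom_image


@pytest.fixture(scope="session")
def band_phantom():
    """Default-geometry band phantom shared by read-only tests."""
    cfg = PhantomConfig(seed=7)
    image, truth = generate_phantom_image(cfg, image_id="band7")
    return cfg, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
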