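import numpy as np
import pytest

from octmap import GrayImage, PhantomParams

# Small phantom frame for unit tests: same 16 x 8 mm field of view as the
# instrument frame but coarsely sampled, keeping the geometry identical
# while the raster is 16x smaller.
SMALL = dict(width_px=256, height_px=64, px_mm_x=16.0 / 256, px_mm_y=8.0 / 64)


@pytest.fixture
def small_params() -> PhantomParams:
    return PhantomParams(**SMALL, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng) -> GrayImage:
    pix = rng.integers(0, 256, size=(24, 32)).astype(float)
    return GrayImage(pix, px_mm_x=0.05, px_mm_y=0.05, image_id="rand")
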