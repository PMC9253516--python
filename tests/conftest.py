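import numpy as np
import pytest

from cpcquant.synthetic import ImageScene, SpotTruth


@pytest.fixture
def single_spot_scene() -> ImageScene:
    """64x64 noise-free two-channel scene with one centered Gaussian focus."""
    return ImageScene(
        width_px=64,
        height_px=64,
        pixel_size_um=0.0645,
        channels=("ACA", "marker"),
        spots=[
            SpotTruth(
                centroid_um=(2.0, 2.0),
                sigma_um=0.15,
                amplitude={"ACA": 1000.0, "marker": 500.0},
            )
        ],
        background_level=100.0,
        gaussian_sd=0.0,
        seed=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
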