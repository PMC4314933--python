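import numpy as np
import pytest

from afmetrics import HeightMap, make_blob


@pytest.fixture
def flat_map():
    """Featureless 1.0 nm surface, 16x16, 1 nm pixels."""
    return HeightMap(
        heights=np.full((16, 16), 1.0),
        pixel_size_x=1.0,
        pixel_size_y=1.0,
    )


@pytest.fixture
def blob_map():
    """Centered Gaussian blob (sigma 3 px, 2 nm) on a zero background."""
    hmap, truth = make_blob((64, 64), (31.5, 31.5), sigma_px=3.0, amplitude_nm=2.0)
    return hmap, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20151)
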