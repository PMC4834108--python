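import numpy as np
import pytest

from rifm.io import RetinalImage
from rifm.localization import LocalizationConfig
from rifm.regions import build_region_mask, crop_disc
from rifm.synthetic import SyntheticSpec, generate_eye


@pytest.fixture(scope="session")
def normal_eye():
    return generate_eye(SyntheticSpec(seed=1, cdr=0.3))


@pytest.fixture(scope="session")
def glaucoma_eye():
    return generate_eye(SyntheticSpec(seed=2, cdr=0.8, ppa=True))


@pytest.fixture(scope="session")
def loc_cfg():
    """Localisation config scaled to the synthetic disc geometry."""
    return LocalizationConfig.for_disc_diameter(50.0, sigma=2.0, w_max=10)


@pytest.fixture(scope="session")
def region_fixture(glaucoma_eye):
    """A disc-centred crop with its ground-truth region mask."""
    img, gt = glaucoma_eye
    crop, offset, _ = crop_disc(img, gt.disc_center, 120)
    local = gt.disc_contour - np.asarray(offset, float)
    rmask = build_region_mask(crop.shape, local, gt.eye_side)
    return crop, rmask


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def flat_image():
    return RetinalImage(np.full((96, 96, 3), 0.5))
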