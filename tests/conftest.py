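import numpy as np
import pytest

from cimaug import (
    BinaryMask,
    FixtureConfig,
    LabeledImage,
    RgbImage,
    SoftLabel,
    extract_lesion,
)
from cimaug.fixtures import make_labeled_sets, make_lesion_image, make_mucosa_image
from cimaug.regions import RegionConfig

#: Small working resolution used throughout the suite; the generator scales
#: its texture and blob geometry with the frame.
SMALL = (48, 48)


def small_fixture_cfg(seed: int = 11) -> FixtureConfig:
    return FixtureConfig(image_size=SMALL, texture_scale=4.0, seed=seed)


@pytest.fixture(scope="session")
def fixture_cfg() -> FixtureConfig:
    return small_fixture_cfg()


@pytest.fixture(scope="session")
def mucosa(fixture_cfg) -> RgbImage:
    return make_mucosa_image(fixture_cfg, np.random.default_rng(1))


@pytest.fixture(scope="session")
def lesion_pair(fixture_cfg):
    return make_lesion_image(fixture_cfg, np.random.default_rng(2))


@pytest.fixture(scope="session")
def lesion_instance(lesion_pair):
    img, mask = lesion_pair
    return extract_lesion(img, mask, source_id="fixture-lesion")


@pytest.fixture(scope="session")
def small_sets(fixture_cfg):
    """25 normal + 10 lesion labelled images at the small resolution."""
    return make_labeled_sets(fixture_cfg, 25, 10)


@pytest.fixture(scope="session")
def region_cfg() -> RegionConfig:
    return RegionConfig(ms_max_samples=600, n_segments=32)


@pytest.fixture(scope="session")
def sweep(small_sets, region_cfg):
    """Full variant sweep over the small fixture dataset (shared: expensive)."""
    from cimaug import ProtocolConfig, variant_sweep

    normals, lesions = small_sets
    return variant_sweep(
        normals, lesions, ProtocolConfig(resize_to=SMALL), seed=9, region_cfg=region_cfg
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_labeled(shape, rng, cls=0, source_id=""):
    img = RgbImage(rng.random((*shape, 3)))
    return LabeledImage(img, SoftLabel.one_hot(cls, 2), None, source_id)
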