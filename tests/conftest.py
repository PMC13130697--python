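import dataclasses

import numpy as np
import pytest

from ccband import PipelineConfig, RgbImage, SyntheticSpec, generate_dataset
from ccband.evaluation import AnnotatedImage
from ccband.segmentation import scaled_superpixel_count


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A 64x64 random RGB image."""
    return RgbImage(rng.random((64, 64, 3)))


@pytest.fixture(scope="session")
def quarter_spec():
    return SyntheticSpec().quarter_scale()


@pytest.fixture(scope="session")
def quarter_config(quarter_spec):
    cfg = PipelineConfig()
    cfg.slic = dataclasses.replace(
        cfg.slic,
        k=scaled_superpixel_count(quarter_spec.height_px, quarter_spec.width_px),
    )
    return cfg


@pytest.fixture(scope="session")
def quarter_samples(quarter_spec):
    """Three quarter-scale synthetic samples, reused across tests."""
    return generate_dataset(quarter_spec, 3, 7)


@pytest.fixture(scope="session")
def annotated_samples(quarter_samples):
    return [AnnotatedImage.from_sample(s) for s in quarter_samples]
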