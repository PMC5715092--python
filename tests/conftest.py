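import numpy as np
import pytest

from wellcount import ArtifactModel, WellGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_artifacts():
    """No debris, no defocus, no noise, no illumination offset."""
    return ArtifactModel(
        debris_prob=0.0,
        defocus_prob=0.0,
        noise_sigma=0.0,
        intensity_offset_range=(0.0, 0.0),
    )


@pytest.fixture
def small_square():
    return WellGeometry(shape="square", image_side=64)


@pytest.fixture
def small_round():
    return WellGeometry(shape="round", image_side=64)
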