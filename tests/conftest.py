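import numpy as np
import pytest

from zfinject.fixtures import FIXTURE_LEVELS, generate_plate
from zfinject.segmentation import CLASSES, IntensitySegmenter


@pytest.fixture(scope="session")
def segmenter():
    """Classical per-pixel segmenter matched to the fixture gray levels."""
    return IntensitySegmenter(levels=FIXTURE_LEVELS, classes=CLASSES)


@pytest.fixture(scope="session")
def single_larva_plate():
    return generate_plate(1, (300, 300), seed=1)


@pytest.fixture(scope="session")
def small_plate():
    return generate_plate(5, (700, 700), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
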