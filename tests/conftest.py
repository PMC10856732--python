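import numpy as np
import pytest

from retloc import (
    AcquisitionSpec,
    CanonicalFrame,
    LandmarkRecord,
    Laterality,
    Point2D,
)


@pytest.fixture
def frame() -> CanonicalFrame:
    return CanonicalFrame()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240130)


def random_landmark(rng: np.random.Generator, image_id: str = "img") -> LandmarkRecord:
    """A valid random landmark record with well-separated landmarks."""
    w = int(rng.integers(600, 2000))
    h = int(rng.integers(600, 2000))
    while True:
        disc = Point2D(float(rng.uniform(50, w - 50)), float(rng.uniform(50, h - 50)))
        mac = Point2D(float(rng.uniform(50, w - 50)), float(rng.uniform(50, h - 50)))
        if disc.distance_to(mac) > 50:
            break
    lat = Laterality.RIGHT if rng.random() < 0.5 else Laterality.LEFT
    return LandmarkRecord(image_id, disc, mac, lat, w, h)


@pytest.fixture
def small_acquisition() -> AcquisitionSpec:
    return AcquisitionSpec(n_images=6, source_size_range=(600, 900))
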