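import numpy as np
import pytest

from labradiomics import LabelMap, PhantomConfig, generate_phantom
from labradiomics.volio import RegionExtract


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig()


@pytest.fixture(scope="session")
def phantom_pair(default_config):
    """One seeded phantom (volume, label map) shared across tests."""
    return generate_phantom(default_config, seed=7)


@pytest.fixture()
def random_region() -> RegionExtract:
    """A small random region with an irregular (but majority-true) mask."""
    rng = np.random.default_rng(11)
    crop = rng.normal(50.0, 5.0, size=(9, 8, 7))
    mask = rng.random((9, 8, 7)) < 0.7
    # keep the bounding box tight: force corners on
    for corner in np.ndindex(2, 2, 2):
        mask[tuple(-1 if c else 0 for c in corner)] = True
    return RegionExtract(crop, mask, (0, 0, 0), (0.4, 0.4, 0.4))


def digitized_sphere(radius_mm: float, spacing: float, margin: int = 3):
    """Binary sphere mask embedded as label 1 in a LabelMap (test oracle input)."""
    n = int(2 * radius_mm / spacing) + 2 * margin + 1
    ax = (np.arange(n) - (n - 1) / 2) * spacing
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    lab = (d2 <= radius_mm**2).astype(np.uint8)
    return LabelMap(lab, (spacing,) * 3)


@pytest.fixture()
def sphere_factory():
    return digitized_sphere
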