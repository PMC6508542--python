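import numpy as np
import pytest

from leafmorph.data_model import LandmarkConfig, Outline
from leafmorph.synthetic import SimParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def leaf_outline() -> Outline:
    """A lobed, asymmetric closed polyline (no special symmetry, so
    normalization tie-breaks are stable)."""
    th = np.linspace(0, 2 * np.pi, 80, endpoint=False)
    r = 1 + 0.25 * np.cos(3 * th) + 0.1 * np.sin(5 * th)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    return Outline(pts)


@pytest.fixture
def random_config(rng) -> LandmarkConfig:
    return LandmarkConfig(rng.normal(size=(15, 2)))


@pytest.fixture(scope="session")
def noise_free_dataset():
    """One vine per species, zero noise: the generator's deterministic core."""
    return generate_dataset(
        SimParams(seed=5, shape_noise_sd=0.0, vines_per_species=1),
        with_outlines=False,
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default study design (8 species x 5 vines x 10 nodes)."""
    return generate_dataset(SimParams(seed=7))
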