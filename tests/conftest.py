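import numpy as np
import pytest

from eus_smt.gist_extract import ExtractionConfig
from eus_smt.lipoma_extract import LipomaConfig
from eus_smt.phantom import PhantomSpec, TumorClass, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def extraction_cfg():
    return ExtractionConfig()


@pytest.fixture
def lipoma_cfg():
    return LipomaConfig()


@pytest.fixture(scope="session")
def gist_phantom():
    """One mid-gray, speckled (GIST-like) lesion on a dark background."""
    spec = PhantomSpec(
        tumor_class=TumorClass.GIST,
        center=(80.0, 150.0),
        axes=(30.0, 24.0),
        rotation_deg=25.0,
        interior_mean=65.0,
        interior_sd=70.0,
        seed=7,
    )
    img, mask = generate_phantom(spec)
    return spec, img, mask


@pytest.fixture(scope="session")
def lipoma_phantom():
    """One bright, strongly speckled (lipoma-like) lesion."""
    spec = PhantomSpec(
        tumor_class=TumorClass.LIPOMA,
        center=(160.0, 90.0),
        axes=(28.0, 33.0),
        rotation_deg=100.0,
        interior_mean=150.0,
        interior_sd=100.0,
        seed=11,
    )
    img, mask = generate_phantom(spec)
    return spec, img, mask


@pytest.fixture(scope="session")
def cyst_phantom():
    """One dark, smooth (cyst-like) lesion."""
    spec = PhantomSpec(
        tumor_class=TumorClass.CYST,
        center=(150.0, 160.0),
        axes=(26.0, 30.0),
        rotation_deg=60.0,
        interior_mean=25.0,
        interior_sd=15.0,
        seed=13,
    )
    img, mask = generate_phantom(spec)
    return spec, img, mask
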