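import numpy as np
import pytest

from histossm.stain_norm import DEFAULT_STAIN_MATRIX
from histossm.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """30 patients x 10 tiles at 64 px, shared across tests."""
    spec = CohortSpec(n_patients=30, tiles_per_patient=10, tile_size=64, seed=1)
    tiles, manifest = generate_cohort(spec)
    return tiles, manifest


@pytest.fixture(scope="session")
def manifest_200():
    """Manifest-only cohort of 200 patients x 5 tiles (split testing)."""
    spec = CohortSpec(n_patients=200, tiles_per_patient=5, tile_size=8, seed=2)
    _, manifest = generate_cohort(spec, render=False)
    return manifest


@pytest.fixture
def stain_matrix():
    return DEFAULT_STAIN_MATRIX.copy()
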