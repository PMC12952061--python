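import numpy as np
import pytest

from ghostcbir import SyntheticDatasetSpec, SyntheticEmbeddingSpec, gen_synthetic_mri


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_records():
    """Default synthetic slice dataset: 3 classes x 6 patients x 6 slices."""
    return gen_synthetic_mri(SyntheticDatasetSpec(seed=7))


@pytest.fixture(scope="session")
def small_embedding_world():
    """Low-dimensional class-structured gallery + held-out queries."""
    from ghostcbir import gen_embedding_gallery
    spec = SyntheticEmbeddingSpec(dim=16, patients_per_class=6,
                                  slices_per_patient=4, separation=4.0, seed=3)
    return gen_embedding_gallery(spec)
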