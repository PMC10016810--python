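import numpy as np
import pytest

from disconnectome.phantom import PhantomConfig, generate_cohort, generate_phantom
from disconnectome.pipeline import compute_measure_table
from disconnectome.virtual_lesion import Parcellation, StreamlineCache


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """Minute-scale phantom used across the unit tests."""
    return PhantomConfig(
        grid_shape=(16, 16, 16),
        n_regions=12,
        n_healthy=6,
        n_streamlines=600,
        n_patients=14,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_config):
    parc, healthy = generate_phantom(small_config)
    return parc, healthy


@pytest.fixture(scope="session")
def small_caches(small_config, small_phantom):
    parc, healthy = small_phantom
    return [StreamlineCache.precompute(s, parc) for s in healthy]


@pytest.fixture(scope="session")
def small_cohort(small_config, small_phantom, small_caches):
    parc, healthy = small_phantom
    return generate_cohort(small_config, parc, healthy, caches=small_caches)


@pytest.fixture(scope="session")
def small_measures(small_cohort, small_caches, small_config):
    return compute_measure_table(small_cohort, small_caches, seed=small_config.seed)


@pytest.fixture
def tiny_parcellation() -> Parcellation:
    """4-region 8x8x8 parcellation, two regions per hemisphere."""
    labels = np.zeros((8, 8, 8), dtype=np.int32)
    labels[:4, :, :4] = 1
    labels[:4, :, 4:] = 2
    labels[4:, :, :4] = 3
    labels[4:, :, 4:] = 4
    return Parcellation(label_volume=labels)
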