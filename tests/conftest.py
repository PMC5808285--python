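import numpy as np
import pytest

from hsiduct import PhantomConfig, RunConfig, default_spectral_model, iter_cohort


def make_cube_array(rng, rows=5, cols=4, bands=6):
    return rng.uniform(0.0, 1.0, size=(rows, cols, bands)).astype(np.float32)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_grid():
    return np.linspace(461.0, 641.0, 31)


@pytest.fixture(scope="session")
def small_phantom_config():
    return PhantomConfig(
        n_patients=3, rows=80, cols=64, cancer_area_fraction=0.35, seed=7
    )


@pytest.fixture(scope="session")
def small_run_config(small_phantom_config):
    return RunConfig(
        phantom=small_phantom_config,
        roi_side=5,
        n_regions=4,
        n_measurements=10,
        subsample_size=16,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_phantom_config):
    return list(iter_cohort(small_phantom_config))


@pytest.fixture(scope="session")
def spectral_model():
    return default_spectral_model()
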