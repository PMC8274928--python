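import numpy as np
import pytest

import vesselmech as vm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy synthetic cohort (4 locations x 2 young + 3 old horses)."""
    meas, truth = vm.gen_inflation_dataset(None, 2, 3, seed=42)
    return meas, truth


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free, zero-between-horse cohort: the fit oracle."""
    profiles = vm.default_profiles(between_horse=False, diameter_noise=0.0)
    meas, truth = vm.gen_inflation_dataset(profiles, 2, 2, seed=7)
    return meas, truth


@pytest.fixture(scope="session")
def histo_table():
    return vm.gen_histology_dataset(None, 3, 4, seed=11)


def random_valid_params(rng, n=1):
    """Random parameters across the physiologically plausible ranges."""
    Am = rng.uniform(50, 4000, n)
    P0 = rng.uniform(40, 200, n)
    P1 = rng.uniform(10, 150, n)
    return [vm.ArctanParams(a, b, c) for a, b, c in zip(Am, P0, P1)]
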