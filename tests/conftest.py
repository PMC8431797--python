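import numpy as np
import pytest

import fieldqsar as fq


@pytest.fixture(scope="session")
def reference_records():
    return fq.load_reference_compounds()


@pytest.fixture(scope="session")
def reference_predictions():
    return fq.load_reference_predictions()


@pytest.fixture(scope="session")
def small_library():
    """A compact congeneric library shared by structure-level tests."""
    return fq.generate_library(
        fq.SyntheticSpec(seed=7, n_molecules=12, ra_pool_size=3, rb_pool_size=3))


@pytest.fixture(scope="session")
def noiseless_library():
    """Noise-free library whose activity is exactly linear in pool choice."""
    return fq.generate_library(
        fq.SyntheticSpec(seed=3, n_molecules=30, noise_sd=0.0,
                         ra_pool_size=4, rb_pool_size=3))


@pytest.fixture(scope="session")
def ref_pharmacophore():
    return fq.reference_pharmacophore()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
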