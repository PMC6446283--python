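import numpy as np
import pytest

from natsc import (
    default_library,
    default_phantom_config,
    simulate_cohort,
)
from natsc.phantom import zero_variability


@pytest.fixture(scope="session")
def lib_acq():
    return default_library()


@pytest.fixture(scope="session")
def lib(lib_acq):
    return lib_acq[0]


@pytest.fixture(scope="session")
def acq(lib_acq):
    return lib_acq[1]


@pytest.fixture(scope="session")
def phantom_config(lib):
    return default_phantom_config(lib)


@pytest.fixture(scope="session")
def degenerate_cohort(lib, phantom_config):
    """Zero-variability, noiseless, motion-free 4-subject cohort."""
    cfg = zero_variability(phantom_config)
    return simulate_cohort(n_subjects=4, seed=11, config=cfg, lib=lib)


@pytest.fixture(scope="session")
def default_cohort(lib, phantom_config):
    """Small cohort under the default study conditions (noise, drift,
    repositioning, laterality offset)."""
    return simulate_cohort(n_subjects=6, seed=7, config=phantom_config, lib=lib)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
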