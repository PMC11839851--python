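import numpy as np
import pytest

from spectvote.cohort import CohortConfig, generate_cohort
from spectvote.network import ArchitectureSpec


@pytest.fixture(scope="session")
def small_cohort():
    """40 scans, enough to contain unanimous and (usually) discrepant votes."""
    return generate_cohort(CohortConfig(n_scans=40, seed=7))


@pytest.fixture(scope="session")
def tiny_arch():
    """A very small network for fast training smoke tests."""
    return ArchitectureSpec(input_size=32, width_multiplier=0.125)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
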