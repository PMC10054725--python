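import logging

import numpy as np
import pytest

from bmfqsar.fixtures import SyntheticSpec, synthetic_study

logging.getLogger("bmfqsar").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_study():
    """Compact synthetic study shared across statistical tests."""
    spec = SyntheticSpec(n_molecules=60, pool_size=25, seed=7)
    ds, X, y, truth = synthetic_study(spec)
    return ds, X, y, truth


@pytest.fixture
def rng():
    """Fresh deterministic generator per test (order-independent)."""
    return np.random.default_rng(20230209)
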