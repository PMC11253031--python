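from __future__ import annotations

import numpy as np
import pytest

from thadisloc import default_params, generate_registry


@pytest.fixture(scope="session")
def small_bundle():
    """A small default-parameter bundle shared across read-only tests."""
    return generate_registry(default_params(cohort_n=800), seed=11)


@pytest.fixture(scope="session")
def default_sim_params():
    return default_params()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
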