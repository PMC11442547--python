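"""Shared fixtures: small deterministic phantoms and toy volumes."""

import numpy as np
import pytest

from collimap.io import PerfusionSeries
from collimap.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Small noise-free phantom used across phase/preprocess tests."""
    return make_phantom(PhantomSpec(grid=(40, 8, 32, 32), noise_sigma=0.0, seed=7))


@pytest.fixture(scope="session")
def default_phantom():
    """Default-grid phantom with realistic noise."""
    return make_phantom(PhantomSpec(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_series(rng):
    data = rng.uniform(50.0, 150.0, size=(6, 4, 10, 12))
    return PerfusionSeries(data=data, dt_seconds=1.6, subject_id="toy")
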