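import numpy as np
import pytest

import plastinet as pn


@pytest.fixture(scope="session")
def quick_calib() -> pn.CalibrationResult:
    """Session-wide leak-conductance calibration (150 s per grid point)."""
    return pn.fit_rate_curve(duration=150_000.0, rng_seed=1234)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(98765)


@pytest.fixture()
def two_neuron() -> pn.BuiltNetwork:
    return pn.fixture_network("two_neuron", rng_seed=7)


@pytest.fixture()
def lattice_36() -> pn.BuiltNetwork:
    return pn.fixture_network("lattice_36", rng_seed=7)
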