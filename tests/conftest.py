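import numpy as np
import pytest

import c8fate as cf


@pytest.fixture(scope="session")
def params():
    """Calibrated population parameters (default anchors)."""
    return cf.calibrate_population()


@pytest.fixture(scope="session")
def dataset25(params):
    """A 300-cell half-killing (25 ng/ml) synthetic dataset."""
    return cf.generate_dataset(params, cf.Scenario("TRAIL_25", 25.0), 300, seed=1234)


@pytest.fixture(scope="session")
def fits25(dataset25):
    """Fits table for the 300-cell half-killing dataset."""
    return cf.fit_trajectories(dataset25.trajectories)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
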