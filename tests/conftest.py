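import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import blisscreen as b

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def design():
    return b.ScreenDesign()


@pytest.fixture
def noiseless_truth():
    """10-gene screen, 3 planted synergies (s=0.5, g=0.8, b=0.6), no noise."""
    return b.SimTruth.random(10, n_synergy=3, s=0.5, noise_cv=0.0, seed=7)


@pytest.fixture
def noiseless_wells(noiseless_truth):
    wells, truth = b.simulate_screen(None, noiseless_truth)
    return wells, truth


@pytest.fixture
def null_grid():
    """Noiseless Bliss-independent checkerboard (no planted deviation)."""
    grid, _ = b.simulate_checkerboard(80.0, 1.5, 6.0, 1.2, noise_cv=0.0, n_reps=1)
    return grid
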