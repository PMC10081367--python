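"""Shared fixtures: synthetic sessions analyzed once per test run."""

import numpy as np
import pytest

from reorient.evaluation import SessionAnalysis
from reorient.synth import SessionConfig


@pytest.fixture(scope="session")
def default_analysis() -> SessionAnalysis:
    """Default study conditions: 200 cells, 15% FS, 3 days x 12 trials."""
    return SessionAnalysis(SessionConfig(seed=7))


@pytest.fixture(scope="session")
def rho1_analysis() -> SessionAnalysis:
    """Deterministic orientation-dig coupling (every C/G dig follows the
    latent map orientation)."""
    return SessionAnalysis(SessionConfig(coupling_rho=1.0, seed=11))


@pytest.fixture(scope="session")
def rho0_analysis() -> SessionAnalysis:
    """No orientation-dig coupling: digs carry no heading information.

    A non-learning animal also digs C and G equally (the geometry-only
    pattern), so the dig schedule here is the day-1 pattern on every
    day; that balance is what makes 0.5 the chance accuracy.
    """
    return SessionAnalysis(
        SessionConfig(
            coupling_rho=0.0,
            dig_probs_by_day=((0.40, 0.40, 0.10, 0.10),) * 3,
            seed=13,
        )
    )


def smooth_random_map(rng, shape=(20, 30), sigma=3.0):
    """Asymmetric smooth positive map (NaN-free) for rotation tests."""
    from scipy.ndimage import gaussian_filter

    # a smoothed random field is asymmetric almost surely; rescale to
    # unit range so smoothing cannot flatten small grids into constants
    m = gaussian_filter(rng.random(shape), sigma)
    return (m - m.min()) / (m.max() - m.min())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
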