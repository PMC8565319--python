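import numpy as np
import pytest

from dropfret.decay import InstrumentResponse
from dropfret.synth import ExperimentDesign, default_signatures


@pytest.fixture(scope="session")
def signatures():
    """Reference species signatures (with the intermediate lifetime set)."""
    return default_signatures()


@pytest.fixture(scope="session")
def irf():
    """Shortest-window instrument response used throughout the synthetic data."""
    return InstrumentResponse(sigma=0.01, t0=0.1)


@pytest.fixture
def small_design():
    """Light-weight design for fast tests (reduced photon budget and bins)."""
    return ExperimentDesign(sl0=3.6, p0=12.0, n_bins=500, counts_per_curve=2e5,
                            seed=0, experiment_id="test")


def mixture_fractions(n=10, beta_max=0.4):
    """Reaction-time grid with IC fraction ramping 0.05 -> beta_max."""
    T = np.geomspace(0.1, 10.0, n)
    beta = np.linspace(0.05, beta_max, n)
    alpha = np.linspace(0.05, 0.5, n)
    return [(float(t), (float(1 - a - b), float(b), float(a)))
            for t, a, b in zip(T, alpha, beta)]
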