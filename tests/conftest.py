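import numpy as np
import pytest

from ladsim import SimulationParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Small confined system for fast structural tests."""
    return SimulationParameters(n_beads=100, rng_seed=7, timestep=2e-4).with_phi(0.2)


def make_semiflexible_chains(n_chains, n_beads, cos_alpha, seed):
    """Freely rotating chains with exact tangent correlation (cos alpha)^s.

    Each bond has unit length and makes a fixed angle alpha with its
    predecessor, with uniformly random azimuth, so the tangent
    autocorrelation is exactly exponential — an independent geometric
    oracle for the persistence-length fit.
    """
    rng = np.random.default_rng(seed)
    chains = np.empty((n_chains, n_beads, 3))
    sin_alpha = np.sqrt(1.0 - cos_alpha**2)
    for c in range(n_chains):
        t = rng.normal(size=3)
        t /= np.linalg.norm(t)
        pos = np.zeros((n_beads, 3))
        for i in range(1, n_beads):
            # random unit vector orthogonal to t
            v = rng.normal(size=3)
            v -= np.dot(v, t) * t
            v /= np.linalg.norm(v)
            t = cos_alpha * t + sin_alpha * v
            t /= np.linalg.norm(t)
            pos[i] = pos[i - 1] + t
        chains[c] = pos
    return chains
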