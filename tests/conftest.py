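"""Shared fixtures: expensive 98-node simulations are session-scoped so
the regime, intervention and contract tests reuse the same runs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from epiprop.detection import analyze_trajectory
from epiprop.epileptor import EpileptorParams, simulate
from epiprop.synthetic import SyntheticSpec, make_synthetic_connectome

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

#: Simulation seed used for the shared surrogate runs.
RUN_SEED = 42
#: Horizon long enough for a full recruitment cascade on the surrogate.
SWEEP_DURATION = 6000.0


def run_seizure(C, ez, seed=RUN_SEED, duration=SWEEP_DURATION, sigma=0.0025):
    """Simulate a single-EZ seizure and return its onset table."""
    params = EpileptorParams.for_network(
        C.n_nodes, [ez], sigma=sigma, duration=duration, seed=seed
    )
    traj = simulate(C, params)
    return analyze_trajectory(traj, [ez])


@pytest.fixture(scope="session")
def surrogate0():
    """The default 98-node mouse-shaped surrogate (generator seed 0)."""
    return make_synthetic_connectome(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def baseline_table0(surrogate0):
    """Onset table of the reference widespread seizure: EZ = the
    high-weight focus node of the seed-0 surrogate."""
    return run_seizure(surrogate0, ez=0)


def random_connectome_weights(rng, n):
    """A random nonnegative weight matrix with zero diagonal."""
    W = rng.random((n, n)) * (rng.random((n, n)) < 0.7)
    np.fill_diagonal(W, 0.0)
    return W
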