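"""Shared experiment fixtures.

The pruning experiments are the expensive part of the suite, so completed
runs are computed once per session and shared: a tiny N=12 run for exact
(exhaustive) checks, N=50 and N=100 runs for the statistical properties,
and one full dual-attractor run on the N=50 skeleton.
"""

import numpy as np
import pytest

import attractorprune as ap


@pytest.fixture(scope="session")
def run12():
    """Tiny single-attractor pruning run, small enough for 2^N enumeration."""
    return ap.single_attractor_experiment(12, seed=303)


@pytest.fixture(scope="session")
def run20():
    """Small run that still verifies as a dual-attractor substrate (at N=12
    the two-pattern construction has reachable spurious mixture states)."""
    return ap.single_attractor_experiment(20, seed=5, n_starts=50)


@pytest.fixture(scope="session")
def run50():
    return ap.single_attractor_experiment(50, seed=101)


@pytest.fixture(scope="session")
def runs50(run50):
    """Three independent N=50 runs (first one shared with ``run50``)."""
    return [run50] + [ap.single_attractor_experiment(50, seed=s) for s in (102, 103)]


@pytest.fixture(scope="session")
def runs100():
    """Ten independent N=100 runs for aggregate degree statistics."""
    return [ap.single_attractor_experiment(100, seed=s) for s in range(10)]


@pytest.fixture(scope="session")
def dual50(run50):
    """Full dual-attractor graft-and-prune run on the N=50 skeleton."""
    return ap.dual_attractor_experiment(run50["tstar"], run50["s"], seed=202)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
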