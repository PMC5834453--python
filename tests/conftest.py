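"""Shared fixtures: ground truths, sessions and fitted models.

Expensive fits are session-scoped so several test modules can reuse them.
"""

import numpy as np
import pytest

from semgmoe.moe import BayesianMixtureOfExperts
from semgmoe.synthetic import make_ground_truth, sample_session


@pytest.fixture(scope="session")
def gt3():
    """Three well-separated experts in 4-D feature / 2-D force space."""
    return make_ground_truth(3, 4, 2, separation=8.0, seed=42)


@pytest.fixture(scope="session")
def sess3(gt3):
    """Training session from gt3: 3 reps x 250 rows per movement, no rest."""
    return sample_session(gt3, n_per_block=250, n_repetitions=3,
                          rest_fraction=0.0, seed=43)


@pytest.fixture(scope="session")
def sess3_test(gt3):
    """Held-out session from gt3 (independent draw)."""
    return sample_session(gt3, n_per_block=150, n_repetitions=1,
                          rest_fraction=0.0, seed=44)


@pytest.fixture(scope="session")
def fitted3(sess3):
    """Overcomplete fit of the 3-expert session: 10 initial experts,
    20 restarts, best lower bound kept."""
    return BayesianMixtureOfExperts(
        n_experts=10, n_restarts=20, random_state=0).fit(sess3.X, sess3.Y)


@pytest.fixture(scope="session")
def gt2():
    """Two experts in 3-D feature / 2-D force space (fast fits)."""
    return make_ground_truth(2, 3, 2, separation=8.0, seed=5)


@pytest.fixture(scope="session")
def sess2(gt2):
    return sample_session(gt2, n_per_block=300, n_repetitions=2,
                          rest_fraction=0.0, seed=6)


@pytest.fixture(scope="session")
def fitted2(sess2):
    return BayesianMixtureOfExperts(
        n_experts=2, n_restarts=2, random_state=0).fit(sess2.X, sess2.Y)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
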