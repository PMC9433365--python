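import itertools

import numpy as np
import pytest

from censmix import GameConfig, SimConfig, recovery_params, simulate


@pytest.fixture(scope="session")
def set1_params():
    """Two-segment truth of the first recovery parameter set."""
    return recovery_params("1")


@pytest.fixture(scope="session")
def small_sim(set1_params):
    """A small simulated trial table (120 persons x 8 trials)."""
    return simulate(SimConfig(n_persons=120, n_trials=8, params=set1_params, seed=42))


def enumerate_joint(z_pmf, config: GameConfig):
    """Exact joint P(Y=k, C=c) by exhaustive enumeration over the intention
    and all uniform loss-card placements.  Independent oracle for the
    Omega/Theta factorization."""
    n = config.n_cards
    placements = list(itertools.combinations(range(1, n + 1), config.n_loss))
    joint = np.zeros((n + 1, 2))
    for z, pz in enumerate(np.asarray(z_pmf)):
        if pz == 0:
            continue
        for placement in placements:
            first = min(placement) if placement else n + 1
            if first <= z:
                joint[first, 1] += pz / len(placements)
            else:
                joint[z, 0] += pz / len(placements)
    return joint
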