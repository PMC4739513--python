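"""Shared fixtures: simulated data sets and (expensive) fitted models."""

from __future__ import annotations

import numpy as np
import pytest

from hmmar.inference import fit
from hmmar.model import HMMMARConfig, TrainingConfig, build_lag_set
from hmmar.simulate import paper2016_preset, simulate


@pytest.fixture(scope="session")
def sim_small():
    """Ten trials of the three-state scenario: cheap ground-truth data."""
    return simulate(paper2016_preset(n_trials=10, seed=7))


@pytest.fixture(scope="session")
def sim40():
    """Forty trials of the three-state scenario (recovery-study scale)."""
    return simulate(paper2016_preset(n_trials=40, seed=11))


@pytest.fixture(scope="session")
def fitted40(sim40):
    """A converged K=3 fit on the forty-trial data, shared across tests."""
    cfg = HMMMARConfig(
        K=3,
        lagset=build_lag_set(35, 0, "uniform"),
        training=TrainingConfig(max_cycles=100, n_restarts=1, seed=0),
    )
    return fit(sim40.data, cfg)


def best_state_permutation(true_path: np.ndarray, hard: np.ndarray, K: int):
    """Permutation of fitted labels maximising agreement with the truth."""
    import itertools

    best, best_agree = None, -1.0
    for perm in itertools.permutations(range(K)):
        agree = float(np.mean(np.asarray(perm)[true_path] == hard))
        if agree > best_agree:
            best, best_agree = perm, agree
    return best, best_agree
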