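import numpy as np
import pytest
from scipy.special import ndtr

from penaltyshot.agents import SyntheticShooterParams, generate_dataset
from penaltyshot.design import build_design
from penaltyshot.models import ChangePointPolicy
from penaltyshot.svgp import fit_svgp


@pytest.fixture(scope="session")
def default_dataset():
    """One participant under the default study conditions (~100 trials per
    opponent, default shooter/goalie parameters), with ground truth."""
    params = [SyntheticShooterParams()]
    trials, truth = generate_dataset(1, 108, seed=42, participant_params=params)
    return trials, truth


@pytest.fixture(scope="session")
def default_design(default_dataset):
    trials, _ = default_dataset
    return build_design(trials)


@pytest.fixture(scope="session")
def fitted_policy(default_design):
    """Policy SVGP fitted to the default participant (shared across tests)."""
    return ChangePointPolicy(default_design).fit(
        n_inducing=50, n_iter=6000, seed=0, learning_rate=0.03
    )


@pytest.fixture(scope="session")
def small_trials():
    trials, truth = generate_dataset(2, 8, seed=3)
    return trials, truth


@pytest.fixture(scope="session")
def tiny_gp():
    """Small fitted classifier on 4-D synthetic probit data."""
    rng = np.random.default_rng(2)
    X = rng.normal(size=(600, 4))
    f = 1.5 * np.tanh(X[:, 0]) - X[:, 1]
    y = (rng.random(600) < ndtr(f)).astype(int)
    return fit_svgp(X, y, n_inducing=20, n_iter=800, seed=0)
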