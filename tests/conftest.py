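import numpy as np
import pandas as pd
import pytest

from banditflame.bandit_env import (
    RewardStructure,
    WalkParams,
    generate_reward_structure,
)


@pytest.fixture(scope="session")
def default_params() -> WalkParams:
    return WalkParams()


@pytest.fixture(scope="session")
def structure(default_params) -> RewardStructure:
    return generate_reward_structure(default_params, seed=1)


def make_constant_structure(value: float = 50.0, n_trials: int = 200,
                            best_arm: int | None = None) -> RewardStructure:
    """Noise-free structure: every payoff equals `value`; optionally one arm
    gets a strictly higher latent mean (and payoff) so it is always best."""
    params = WalkParams(n_trials=n_trials)
    means = np.full((n_trials, params.n_arms), float(value))
    if best_arm is not None:
        means[:, best_arm] = value + 10.0
    payoffs = np.clip(np.rint(means), params.payoff_min, params.payoff_max).astype(int)
    return RewardStructure(params=params, latent_means=means, payoffs=payoffs, seed=-1)


def make_structure_from_means(means: np.ndarray) -> RewardStructure:
    means = np.asarray(means, float)
    n_trials, n_arms = means.shape
    params = WalkParams(n_trials=max(n_trials, 2), n_arms=n_arms)
    if n_trials < 2:  # pragma: no cover - guard for toy fixtures
        raise ValueError("need >= 2 trials")
    payoffs = np.clip(np.rint(means), params.payoff_min, params.payoff_max).astype(int)
    return RewardStructure(params=params, latent_means=means, payoffs=payoffs, seed=-1)
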