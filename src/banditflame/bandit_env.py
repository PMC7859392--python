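"""Restless three-armed bandit: reward-structure generation and agent simulation.

The task environment is a bank of slot machines whose mean payoffs drift
from trial to trial as a decaying (mean-reverting) Gaussian random walk,

    mu[t+1, a] = lambda * mu[t, a] + (1 - lambda) * theta + eps,
    eps ~ N(0, diffusion_sd^2),

with the realized payoff on each trial drawn around the latent mean with
independent observation noise, rounded to an integer and clipped to the
displayed point range (1-100 by default).  Because the walk is stationary,
initial means are drawn from the walk's stationary distribution
N(theta, diffusion_sd^2 / (1 - lambda^2)) so early trials are statistically
exchangeable with late ones.

Agents are synthetic choosers used to generate behavior with known
explore/exploit structure: a uniform random chooser (the chance-level null),
a delta-rule softmax learner, a softmax learner with a count-based
exploration bonus, and an epsilon-greedy chooser.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WalkParams",
    "RewardStructure",
    "AgentSpec",
    "ChoiceSequence",
    "generate_reward_structure",
    "simulate_agent",
    "random_chooser_baseline",
]

AGENT_KINDS = ("random", "softmax_q", "softmax_ucb", "epsilon_greedy")


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the decaying Gaussian random walk payoff process."""

    n_arms: int = 3
    n_trials: int = 200
    decay_lambda: float = 0.9836
    decay_center_theta: float = 50.0
    diffusion_sd: float = 2.8
    payoff_noise_sd: float = 4.0
    payoff_min: int = 1
    payoff_max: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.decay_lambda < 1.0):
            raise ValueError(f"decay_lambda must lie in (0, 1), got {self.decay_lambda}")
        if self.diffusion_sd < 0 or self.payoff_noise_sd < 0:
            raise ValueError("diffusion_sd and payoff_noise_sd must be >= 0")
        if self.payoff_min >= self.payoff_max:
            raise ValueError("payoff_min must be < payoff_max")
        if self.n_arms < 2:
            raise ValueError("n_arms must be >= 2")
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")

    @property
    def stationary_sd(self) -> float:
        """SD of the walk's stationary distribution around theta."""
        return self.diffusion_sd / np.sqrt(1.0 - self.decay_lambda**2)


@dataclass(frozen=True)
class RewardStructure:
    """One realized task instance: latent means and integer payoffs per arm/trial."""

    params: WalkParams
    latent_means: np.ndarray  # (n_trials, n_arms), float
    payoffs: np.ndarray  # (n_trials, n_arms), int
    seed: int

    def __post_init__(self) -> None:
        shape = (self.params.n_trials, self.params.n_arms)
        if self.latent_means.shape != shape or self.payoffs.shape != shape:
            raise ValueError("latent_means/payoffs shapes must match params")
        if not np.isfinite(self.latent_means).all():
            raise ValueError("latent means must be finite")
        if self.payoffs.min() < self.params.payoff_min or self.payoffs.max() > self.params.payoff_max:
            raise ValueError("payoffs outside [payoff_min, payoff_max]")

    @property
    def n_trials(self) -> int:
        return self.params.n_trials

    @property
    def n_arms(self) -> int:
        return self.params.n_arms

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: trial and arm are 1-based in CSVs."""
        t, a = np.meshgrid(
            np.arange(self.n_trials), np.arange(self.n_arms), indexing="ij"
        )
        return pd.DataFrame(
            {
                "trial": t.ravel() + 1,
                "arm": a.ravel() + 1,
                "latent_mean": self.latent_means.ravel(),
                "payoff": self.payoffs.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, params: WalkParams | None = None, seed: int = -1) -> "RewardStructure":
        n_trials = int(df["trial"].max())
        n_arms = int(df["arm"].max())
        if params is None:
            params = WalkParams(n_arms=n_arms, n_trials=n_trials)
        means = np.zeros((n_trials, n_arms))
        pay = np.zeros((n_trials, n_arms), dtype=int)
        means[df["trial"] - 1, df["arm"] - 1] = df["latent_mean"]
        pay[df["trial"] - 1, df["arm"] - 1] = df["payoff"]
        return cls(params=params, latent_means=means, payoffs=pay, seed=seed)


@dataclass(frozen=True)
class AgentSpec:
    """Synthetic chooser.

    kind:
        random          -- uniform over arms every trial (chance-level null)
        softmax_q       -- delta-rule value learning, softmax choice
        softmax_ucb     -- softmax_q plus a count-based exploration bonus
                           ucb_bonus_weight / (1 + n_selections[a])
        epsilon_greedy  -- argmax of learned values with lapse rate epsilon

    inverse_temperature is in 1/points: 0 gives uniform choice, large values
    approach greedy.  q_init is the initial value estimate for every arm.
    """

    kind: str = "softmax_q"
    learning_rate: float = 0.35
    inverse_temperature: float = 0.2
    ucb_bonus_weight: float = 0.0
    epsilon: float = 0.1
    q_init: float = 50.0

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}; expected one of {AGENT_KINDS}")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.inverse_temperature < 0:
            raise ValueError("inverse_temperature must be >= 0")
        if self.ucb_bonus_weight < 0:
            raise ValueError("ucb_bonus_weight must be >= 0")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")


@dataclass(frozen=True)
class ChoiceSequence:
    """One subject's ordered choices (0-based arms) and received payoffs."""

    subject_id: str
    choices: np.ndarray  # (n_trials,), int
    received_payoffs: np.ndarray  # (n_trials,), float/int
    structure_seed: int

    def __post_init__(self) -> None:
        if self.choices.shape != self.received_payoffs.shape:
            raise ValueError("choices and received_payoffs must have equal length")
        if self.choices.min() < 0:
            raise ValueError("choices must be non-negative arm indices")

    @property
    def n_trials(self) -> int:
        return self.choices.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "trial": np.arange(self.n_trials) + 1,
                "choice": self.choices + 1,  # 1-based in exports
                "payoff": self.received_payoffs,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChoiceSequence":
        return cls(
            subject_id=str(df["subject_id"].iloc[0]),
            choices=df["choice"].to_numpy(dtype=int) - 1,
            received_payoffs=df["payoff"].to_numpy(),
            structure_seed=-1,
        )


def generate_reward_structure(params: WalkParams, seed: int) -> RewardStructure:
    """Draw one task instance of the decaying Gaussian random walk.

    Deterministic given (params, seed).  The latent mean of each arm starts
    at a draw from the stationary distribution and mean-reverts toward
    theta; realized payoffs add observation noise, then round and clip.
    """
    rng = np.random.default_rng(seed)
    T, A = params.n_trials, params.n_arms
    lam, theta = params.decay_lambda, params.decay_center_theta

    mu = np.empty((T, A))
    mu[0] = rng.normal(theta, params.stationary_sd, size=A)
    steps = rng.normal(0.0, params.diffusion_sd, size=(T - 1, A))
    for t in range(1, T):
        mu[t] = lam * mu[t - 1] + (1.0 - lam) * theta + steps[t - 1]

    noise = rng.normal(0.0, params.payoff_noise_sd, size=(T, A))
    payoffs = np.clip(
        np.rint(mu + noise), params.payoff_min, params.payoff_max
    ).astype(np.int64)
    return RewardStructure(params=params, latent_means=mu, payoffs=payoffs, seed=seed)


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max()
    w = np.exp(z)
    return w / w.sum()


def simulate_agent(structure: RewardStructure, agent: AgentSpec, seed: int,
                   subject_id: str = "sim") -> ChoiceSequence:
    """Simulate one agent on one reward structure; deterministic given seed."""
    rng = np.random.default_rng(seed)
    T, A = structure.n_trials, structure.n_arms
    payoffs = structure.payoffs

    if agent.kind == "random":
        choices = rng.integers(0, A, size=T)
    else:
        q = np.full(A, float(agent.q_init))
        counts = np.zeros(A)
        choices = np.empty(T, dtype=np.int64)
        for t in range(T):
            if agent.kind == "epsilon_greedy":
                if rng.random() < agent.epsilon:
                    c = int(rng.integers(0, A))
                else:
                    c = int(np.argmax(q))  # ties -> lowest index
            else:
                v = q.copy()
                if agent.kind == "softmax_ucb":
                    v += agent.ucb_bonus_weight / (1.0 + counts)
                p = _softmax(agent.inverse_temperature * v)
                c = int(rng.choice(A, p=p))
            r = payoffs[t, c]
            q[c] += agent.learning_rate * (r - q[c])
            counts[c] += 1
            choices[t] = c

    received = payoffs[np.arange(T), choices]
    return ChoiceSequence(
        subject_id=subject_id,
        choices=np.asarray(choices, dtype=np.int64),
        received_payoffs=received,
        structure_seed=structure.seed,
    )


def random_chooser_baseline(
    structures: Sequence[RewardStructure], n_sims: int = 1000, seed: int = 0
) -> tuple[float, np.ndarray]:
    """Monte-Carlo chance-level earnings.

    For each reward structure, simulate ``n_sims`` uniform random choosers
    and average the per-trial payoff.  Returns the grand mean across all
    structures and simulations, plus the per-structure means.
    """
    if len(structures) == 0:
        raise ValueError("need at least one reward structure")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    per_structure = np.empty(len(structures))
    for i, s in enumerate(structures):
        T, A = s.n_trials, s.n_arms
        choices = rng.integers(0, A, size=(n_sims, T))
        drawn = s.payoffs[np.arange(T)[None, :], choices]  # (n_sims, T)
        per_structure[i] = drawn.mean()
    return float(per_structure.mean()), per_structure
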