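"""Model-free classification of bandit choices into exploitation and exploration.

Every trial after the first is labelled by comparing the current choice with
the previous one and with the objective reward structure:

* staying on the arm whose latent mean is currently highest -> exploitation
  of the best option (EXPLOIT_BEST);
* staying on a non-best arm -> STAY_NONBEST;
* switching arms -> exploration, split into
  - directed exploration (SHIFT_DIRECTED): the destination is the least
    selected arm so far (ties for least-selected count as directed) -- a
    goal-directed move toward the most uncertain option, and
  - random exploration (SHIFT_RANDOM): a switch to an already better-sampled
    arm, i.e. decision noise that yields little new information.

An alternative value-based scheme labels a switch from the current best arm
to the current second-best arm as directed and every other switch as random.

"Best" is always judged on the latent walk means (the objective expected
value), never on the noisy realized payoffs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bandit_env import ChoiceSequence, RewardStructure

__all__ = [
    "UNCLASSIFIED",
    "EXPLOIT_BEST",
    "STAY_NONBEST",
    "SHIFT_DIRECTED",
    "SHIFT_RANDOM",
    "TrialLabels",
    "BehavioralMetrics",
    "rank_options",
    "classify_trials",
    "classify_trials_value_based",
    "summarize",
]

UNCLASSIFIED = "UNCLASSIFIED"
EXPLOIT_BEST = "EXPLOIT_BEST"
STAY_NONBEST = "STAY_NONBEST"
SHIFT_DIRECTED = "SHIFT_DIRECTED"
SHIFT_RANDOM = "SHIFT_RANDOM"

LABELS = (UNCLASSIFIED, EXPLOIT_BEST, STAY_NONBEST, SHIFT_DIRECTED, SHIFT_RANDOM)

#: rank codes: 0 = best, 1 = second, ..., n_arms-1 = worst
RANK_NAMES = {0: "best", 1: "second", 2: "worst"}


@dataclass(frozen=True)
class TrialLabels:
    """Per-trial behavioral labels plus the bookkeeping used to derive them."""

    labels: np.ndarray  # (n_trials,), str
    option_rank_per_trial: np.ndarray  # (n_trials, n_arms), int rank codes
    cumulative_counts: np.ndarray  # (n_trials, n_arms), selections before trial t
    scheme: str = "count"

    def __post_init__(self) -> None:
        T = self.labels.shape[0]
        if self.option_rank_per_trial.shape[0] != T or self.cumulative_counts.shape[0] != T:
            raise ValueError("label/rank/count lengths disagree")

    @property
    def n_trials(self) -> int:
        return self.labels.shape[0]


@dataclass(frozen=True)
class BehavioralMetrics:
    """Subject-level summary of bandit behavior.

    mean_points is the average payoff per trial.  exploit_mean_run_length is
    the mean length of maximal runs of choosing the objectively best arm (a
    run breaks when the choice changes or the chosen arm loses best rank).
    n_directed / n_random count labelled shifts; their sum is n_shifts.
    """

    mean_points: float
    exploit_mean_run_length: float
    nonbest_mean_run_length_per_arm_rank: dict
    n_directed: int
    n_random: int
    n_shifts: int
    n_exploit_runs: int

    def __post_init__(self) -> None:
        if self.n_directed + self.n_random != self.n_shifts:
            raise ValueError("shift counts do not add up")


def rank_options(structure: RewardStructure, t: int) -> np.ndarray:
    """Rank arms at trial ``t`` by latent mean, descending.

    Returns an integer array where entry ``a`` is arm ``a``'s rank code
    (0 = best).  Ties break toward the lower arm index.
    """
    if not (0 <= t < structure.n_trials):
        raise IndexError(f"trial index {t} out of range [0, {structure.n_trials})")
    means = structure.latent_means[t]
    # lexsort: primary key -means (descending mean), secondary arm index
    order = np.lexsort((np.arange(len(means)), -means))
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(means))
    return ranks


def _rank_matrix(structure: RewardStructure) -> np.ndarray:
    return np.vstack([rank_options(structure, t) for t in range(structure.n_trials)])


def _cumulative_counts(choices: np.ndarray, n_arms: int) -> np.ndarray:
    """counts[t, a] = number of times arm a was chosen on trials 0..t-1."""
    T = choices.shape[0]
    onehot = np.zeros((T, n_arms), dtype=np.int64)
    onehot[np.arange(T), choices] = 1
    counts = np.zeros((T, n_arms), dtype=np.int64)
    counts[1:] = np.cumsum(onehot, axis=0)[:-1]
    return counts


def _check_compatible(seq: ChoiceSequence, structure: RewardStructure) -> None:
    if seq.n_trials != structure.n_trials:
        raise ValueError(
            f"choice sequence has {seq.n_trials} trials but structure has {structure.n_trials}"
        )
    if seq.choices.max() >= structure.n_arms:
        raise ValueError("choice indices exceed the structure's arm count")


def classify_trials(seq: ChoiceSequence, structure: RewardStructure) -> TrialLabels:
    """Count-based labelling: directed exploration = shift to the least
    selected arm (ties for least count as directed)."""
    _check_compatible(seq, structure)
    ranks = _rank_matrix(structure)
    counts = _cumulative_counts(seq.choices, structure.n_arms)
    labels = np.empty(seq.n_trials, dtype=object)
    labels[0] = UNCLASSIFIED
    for t in range(1, seq.n_trials):
        c, prev = seq.choices[t], seq.choices[t - 1]
        if c == prev:
            labels[t] = EXPLOIT_BEST if ranks[t, c] == 0 else STAY_NONBEST
        else:
            labels[t] = (
                SHIFT_DIRECTED if counts[t, c] == counts[t].min() else SHIFT_RANDOM
            )
    return TrialLabels(labels=labels, option_rank_per_trial=ranks,
                       cumulative_counts=counts, scheme="count")


def classify_trials_value_based(seq: ChoiceSequence, structure: RewardStructure) -> TrialLabels:
    """Value-based labelling: only a switch from the current best arm to the
    current second-best arm counts as directed exploration."""
    _check_compatible(seq, structure)
    ranks = _rank_matrix(structure)
    counts = _cumulative_counts(seq.choices, structure.n_arms)
    labels = np.empty(seq.n_trials, dtype=object)
    labels[0] = UNCLASSIFIED
    for t in range(1, seq.n_trials):
        c, prev = seq.choices[t], seq.choices[t - 1]
        if c == prev:
            labels[t] = EXPLOIT_BEST if ranks[t, c] == 0 else STAY_NONBEST
        else:
            directed = ranks[t, prev] == 0 and ranks[t, c] == 1
            labels[t] = SHIFT_DIRECTED if directed else SHIFT_RANDOM
    return TrialLabels(labels=labels, option_rank_per_trial=ranks,
                       cumulative_counts=counts, scheme="value")


def _run_lengths(mask: np.ndarray, choices: np.ndarray) -> list[int]:
    """Lengths of maximal runs where mask holds and the choice is constant."""
    runs: list[int] = []
    length = 0
    for t in range(len(mask)):
        if mask[t] and (length == 0 or choices[t] == choices[t - 1]):
            length += 1
        else:
            if length:
                runs.append(length)
            length = 1 if mask[t] else 0
    if length:
        runs.append(length)
    return runs


def summarize(labels: TrialLabels, seq: ChoiceSequence, min_run_len: int = 1) -> BehavioralMetrics:
    """Reduce per-trial labels to subject-level metrics.

    ``min_run_len`` controls which maximal best-choice runs enter the mean
    run length (1 keeps all; 2 keeps only runs long enough to constitute
    continuous selection).
    """
    ranks = labels.option_rank_per_trial
    chosen_rank = ranks[np.arange(seq.n_trials), seq.choices]

    exploit_runs = [r for r in _run_lengths(chosen_rank == 0, seq.choices)
                    if r >= min_run_len]
    exploit_mean = float(np.mean(exploit_runs)) if exploit_runs else 0.0

    per_rank: dict[str, float] = {}
    nonbest_all: list[int] = []
    for rank_code in range(1, ranks.shape[1]):
        runs = [r for r in _run_lengths(chosen_rank == rank_code, seq.choices)
                if r >= min_run_len]
        nonbest_all.extend(runs)
        name = RANK_NAMES.get(rank_code, f"rank{rank_code}")
        per_rank[name] = float(np.mean(runs)) if runs else 0.0
    per_rank["pooled"] = float(np.mean(nonbest_all)) if nonbest_all else 0.0

    n_directed = int(np.sum(labels.labels == SHIFT_DIRECTED))
    n_random = int(np.sum(labels.labels == SHIFT_RANDOM))
    return BehavioralMetrics(
        mean_points=float(np.mean(seq.received_payoffs)),
        exploit_mean_run_length=exploit_mean,
        nonbest_mean_run_length_per_arm_rank=per_rank,
        n_directed=n_directed,
        n_random=n_random,
        n_shifts=n_directed + n_random,
        n_exploit_runs=len(exploit_runs),
    )


def labels_frame(labels: TrialLabels, seq: ChoiceSequence) -> pd.DataFrame:
    """Long-format per-trial export (1-based trials/arms)."""
    chosen_rank = labels.option_rank_per_trial[np.arange(seq.n_trials), seq.choices]
    return pd.DataFrame(
        {
            "subject_id": seq.subject_id,
            "trial": np.arange(seq.n_trials) + 1,
            "choice": seq.choices + 1,
            "label": labels.labels,
            "is_best": chosen_rank == 0,
            "cum_count_choice": labels.cumulative_counts[
                np.arange(seq.n_trials), seq.choices
            ],
        }
    )
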