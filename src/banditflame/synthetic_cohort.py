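"""Synthetic study cohort with the statistical structure the analysis assumes.

The generator emulates a two-group case/control study (healthy controls, HC,
n=19 by default vs. patients, SZ, n=45) in which every subject contributes:

* a restless three-armed bandit session (reward structure + choices from a
  delta-rule softmax agent whose decision temperature is group- and
  inflammation-dependent);
* a multiplex immune panel on a log2 scale drawn from a multivariate normal
  whose inverse covariance (precision) is a user-specified sparse matrix,
  with additive group mean shifts on a subset of markers and
  limit-of-detection (LOD) censoring;
* a separately measured hsCRP value (mg/L, log-normal, right-skewed, higher
  in the patient group);
* 30 PANSS item ratings (1-7) from a five-factor model, two cognition
  subtests (letter-number span, symbol coding), and the usual covariates
  (age, sex, BMI, smoking, education, antipsychotic dose, functioning,
  illness course).

The key construction is a per-subject latent inflammation score L ~ N(0,1):
the agent's softmax temperature is ``base + behavior_link * L`` and log
hsCRP gains ``hscrp_latent_load * L``, so random exploration and hsCRP are
positively coupled within groups by design.  The disorganization PANSS
factor loads on the same latent, coupling it to random exploration too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .bandit_env import (
    AgentSpec,
    ChoiceSequence,
    RewardStructure,
    WalkParams,
    generate_reward_structure,
    simulate_agent,
)

__all__ = [
    "DEFAULT_MARKERS",
    "CohortConfig",
    "SubjectRecord",
    "Cohort",
    "default_precision",
    "generate_immune_panel",
    "generate_cohort",
]

# Marker roster: the inflammatory proteins most relevant to the analysis
# (acute-phase signalling, TNF-superfamily ligands, chemokines) plus a few
# null markers and two sparsely detected ones that exercise LOD exclusion.
DEFAULT_MARKERS = (
    "IL-6", "TRAIL", "TRANCE", "FGF-21", "CCL2", "CCL7", "CCL11", "CCL20",
    "SCF", "CXCL11", "CCL28",
    "CXCL1", "IL-18", "CD40",          # no group effect
    "IL-20", "IL-33",                  # mostly below LOD -> excluded downstream
)

# log2 mean shifts (SZ minus HC); positive = elevated in patients.
DEFAULT_MARKER_SHIFTS = {
    "IL-6": 0.7, "TRAIL": 1.0, "TRANCE": 0.6, "FGF-21": 0.6,
    "CCL2": 0.6, "CCL7": 0.7, "CCL11": 0.8, "CCL20": 1.0,
    "SCF": -0.6, "CXCL11": -0.55, "CCL28": -0.6,
}

# LODs on the log2 scale.  Panel marginals are ~N(5, 1); an LOD of 2 censors
# almost nothing, an LOD of 6.3 censors ~90% of values.
DEFAULT_LODS = {m: 2.0 for m in DEFAULT_MARKERS}
DEFAULT_LODS["IL-20"] = 6.3
DEFAULT_LODS["IL-33"] = 6.3

PANSS_P = [f"P{i}" for i in range(1, 8)]
PANSS_N = [f"N{i}" for i in range(1, 8)]
PANSS_G = [f"G{i}" for i in range(1, 17)]
PANSS_ITEMS = PANSS_P + PANSS_N + PANSS_G

# Five-factor item assignment (negative/positive/disorganized/depressive
# factors used downstream; excitement completes the model).
PANSS_FACTOR_ITEMS = {
    "negative": ["N1", "N2", "N3", "N4", "N6", "G7"],
    "positive": ["P1", "P3", "P5", "G9"],
    "disorganized": ["P2", "N5", "G11"],
    "depressive": ["P4", "P7", "G8", "G14"],
    "excitement": ["P4", "G4", "G8", "G14"],  # unused downstream
}


def default_precision(markers: Iterable[str] = DEFAULT_MARKERS) -> pd.DataFrame:
    """Sparse symmetric positive-definite precision matrix over the panel.

    A chain over the group-shifted markers (adjacent partial correlations)
    plus an IL-6 hub edge to CCL2 mimics the mutually regulated cytokine
    milieu; null and low-detection markers stay conditionally independent.
    """
    markers = list(markers)
    p = len(markers)
    omega = np.eye(p)
    idx = {m: i for i, m in enumerate(markers)}
    chain = [m for m in DEFAULT_MARKER_SHIFTS if m in idx]
    for a, b in zip(chain[:-1], chain[1:]):
        omega[idx[a], idx[b]] = omega[idx[b], idx[a]] = -0.35
    if "IL-6" in idx and "CCL2" in idx:
        omega[idx["IL-6"], idx["CCL2"]] = omega[idx["CCL2"], idx["IL-6"]] = -0.25
    # diagonal dominance guarantees positive definiteness
    row_off = np.abs(omega).sum(axis=1) - 1.0
    np.fill_diagonal(omega, 1.0 + row_off + 0.1)
    return pd.DataFrame(omega, index=markers, columns=markers)


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for the synthetic cohort."""

    n_hc: int = 19
    n_sz: int = 45
    seed: int = 0
    walk: WalkParams = field(default_factory=WalkParams)

    # behavior: softmax temperature (points) = base(group) + behavior_link * L
    hc_temperature: float = 3.0
    sz_temperature: float = 8.0
    behavior_link: float = 1.5
    min_temperature: float = 0.5
    learning_rate: float = 0.35

    # immune panel (log2 scale)
    markers: tuple = DEFAULT_MARKERS
    marker_mean: float = 5.0
    marker_shifts: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_SHIFTS))
    lods: dict = field(default_factory=lambda: dict(DEFAULT_LODS))
    n_qc_fail: int = 0

    # hsCRP (mg/L): log-normal with group shift and latent-inflammation load
    hscrp_log_mean: float = 0.0
    hscrp_group_shift: float = 0.7
    hscrp_latent_load: float = 0.7
    hscrp_log_sd: float = 0.6

    # latent inflammation score: N(group shift, 1)
    latent_group_shift: float = 0.5

    # one pre-generated walk instantiation shared by all subjects (the
    # usual practice for this task family); False gives every subject an
    # independent structure
    shared_structure: bool = True

    def __post_init__(self) -> None:
        if self.n_hc < 3 or self.n_sz < 3:
            raise ValueError("need at least 3 subjects per group")
        if self.min_temperature <= 0:
            raise ValueError("min_temperature must be > 0")
        for m in self.marker_shifts:
            if m not in self.markers:
                raise ValueError(f"shift given for unknown marker {m!r}")
        missing = [m for m in self.markers if m not in self.lods]
        if missing:
            raise ValueError(f"missing LOD for markers: {missing}")

    @property
    def n_total(self) -> int:
        return self.n_hc + self.n_sz

    def precision(self) -> pd.DataFrame:
        return default_precision(self.markers)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # "HC" or "SZ"
    agent: AgentSpec
    latent_inflammation: float
    panss_items: dict
    lns_raw: float
    sct_raw: float
    covariates: dict
    immune_panel: dict  # observed log2 values (censored at LOD)
    immune_censored: dict  # marker -> bool, True where value was below LOD
    hscrp: float
    qc_fail: bool = False


@dataclass
class Cohort:
    """Container for one generated cohort plus per-subject task data."""

    config: CohortConfig
    subjects: list
    structures: dict  # subject_id -> RewardStructure
    choices: dict  # subject_id -> ChoiceSequence

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                "group": s.group,
                "qc_fail": s.qc_fail,
                "hscrp": s.hscrp,
                "lns_raw": s.lns_raw,
                "sct_raw": s.sct_raw,
                "latent_inflammation": s.latent_inflammation,
            }
            row.update({f"panss_{k}": v for k, v in s.panss_items.items()})
            row.update(s.covariates)
            row.update(s.immune_panel)
            rows.append(row)
        return pd.DataFrame(rows).set_index("subject_id")

    def panel_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {s.subject_id: s.immune_panel for s in self.subjects}
        ).T.loc[[s.subject_id for s in self.subjects], list(self.config.markers)]

    def censor_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {s.subject_id: s.immune_censored for s in self.subjects}
        ).T.loc[[s.subject_id for s in self.subjects], list(self.config.markers)]

    def groups(self) -> pd.Series:
        return pd.Series({s.subject_id: s.group for s in self.subjects}, name="group")


def generate_immune_panel(
    n: int,
    precision: pd.DataFrame,
    shifts: dict | None,
    lods: dict,
    seed: int,
    mean: float = 5.0,
    group_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw an n-subject panel from N(mean + shift, inv(precision)).

    Returns ``(truth, observed, mask)``: the uncensored draws, the observed
    panel with below-LOD cells floored at the marker's LOD (the instrument
    cannot quantify below its detection floor), and the boolean below-LOD
    mask.  ``group_mask`` marks the subjects receiving the mean shifts (all,
    when omitted).
    """
    markers = list(precision.columns)
    omega = precision.to_numpy(dtype=float)
    if not np.allclose(omega, omega.T):
        raise ValueError("precision matrix must be symmetric")
    try:
        cov = np.linalg.inv(omega)
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix must be positive definite") from exc

    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(np.zeros(len(markers)), cov, size=n,
                                method="cholesky") + mean
    if shifts:
        shift_vec = np.array([shifts.get(m, 0.0) for m in markers])
        if group_mask is None:
            x = x + shift_vec
        else:
            x = x + np.outer(np.asarray(group_mask, dtype=float), shift_vec)

    truth = pd.DataFrame(x, columns=markers)
    lod_vec = np.array([lods[m] for m in markers])
    mask = truth.lt(lod_vec, axis=1)
    observed = truth.clip(lower=pd.Series(lod_vec, index=markers), axis=1)
    return truth, observed, mask


def _panss_items(rng: np.random.Generator, group: str, latent: float) -> dict:
    """Five-factor PANSS item generator; HC sit near the 1-rating floor."""
    if group == "SZ":
        factor_means = {"negative": 1.6, "positive": 0.5, "disorganized": 1.0,
                        "depressive": 0.35, "excitement": 0.3}
    else:
        factor_means = {k: 0.0 for k in PANSS_FACTOR_ITEMS}
    factors = {k: rng.normal(m, 0.6) for k, m in factor_means.items()}
    # disorganization shares the inflammation/decision-noise latent
    factors["disorganized"] += 0.6 * latent
    items = {}
    for item in PANSS_ITEMS:
        load = [factors[f] for f, members in PANSS_FACTOR_ITEMS.items() if item in members]
        f = np.mean(load) if load else 0.0
        items[item] = int(np.clip(np.rint(1.0 + f + rng.normal(0.0, 0.7)), 1, 7))
    return items


def _covariates(rng: np.random.Generator, group: str) -> dict:
    cov = {
        "age": float(np.clip(rng.normal(33.0, 10.0), 18, 65)),
        "sex": str(rng.choice(["male", "female"])),
        "smoking": int(rng.random() < (0.67 if group == "SZ" else 0.42)),
        "education_years": float(np.clip(
            rng.normal(12.3 if group == "SZ" else 14.4, 3.0), 9, 22)),
        "bmi": float(np.clip(
            rng.normal(26.4 if group == "SZ" else 23.4, 4.5), 16, 45)),
        "psp": float(np.clip(
            rng.normal(51.8 if group == "SZ" else 97.0, 10.0), 10, 100)),
    }
    if group == "SZ":
        onset = float(np.clip(rng.normal(23.9, 6.9), 15, min(cov["age"], 60)))
        cov.update(
            cpz_equivalents=float(np.clip(rng.lognormal(5.9, 0.8), 0, 3000)),
            n_hospitalizations=int(rng.poisson(5.4)),
            n_psychotic_episodes=int(1 + rng.poisson(4.3)),
            illness_onset_age=onset,
            illness_duration_months=float(max(1.0, (cov["age"] - onset) * 12.0)),
        )
    else:
        cov.update(cpz_equivalents=0.0, n_hospitalizations=0,
                   n_psychotic_episodes=0, illness_onset_age=np.nan,
                   illness_duration_months=0.0)
    return cov


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full synthetic cohort, reproducible under config.seed."""
    root = np.random.SeedSequence(config.seed)
    ss_panel, ss_subject, ss_task = root.spawn(3)
    n = config.n_total
    groups = ["HC"] * config.n_hc + ["SZ"] * config.n_sz
    group_mask = np.array([g == "SZ" for g in groups])

    truth, _, mask = generate_immune_panel(
        n, config.precision(), config.marker_shifts, config.lods,
        seed=ss_panel.generate_state(1)[0] % (2**31),
        mean=config.marker_mean, group_mask=group_mask,
    )

    rng = np.random.default_rng(ss_subject)

    qc_fail_ids = set()
    if config.n_qc_fail:
        qc_fail_ids = set(rng.choice(n, size=config.n_qc_fail, replace=False))

    subjects: list[SubjectRecord] = []
    structures: dict[str, RewardStructure] = {}
    choices: dict[str, ChoiceSequence] = {}
    for i, group in enumerate(groups):
        sid = f"{'hc' if group == 'HC' else 'sz'}{i:03d}"
        latent = float(rng.normal(
            config.latent_group_shift if group == "SZ" else 0.0, 1.0))

        base_temp = config.sz_temperature if group == "SZ" else config.hc_temperature
        temperature = max(config.min_temperature,
                          base_temp + config.behavior_link * latent)
        agent = AgentSpec(kind="softmax_q", learning_rate=config.learning_rate,
                          inverse_temperature=1.0 / temperature)

        log_crp = (config.hscrp_log_mean
                   + (config.hscrp_group_shift if group == "SZ" else 0.0)
                   + config.hscrp_latent_load * latent
                   + rng.normal(0.0, config.hscrp_log_sd))
        hscrp = float(np.exp(log_crp))

        if group == "SZ":
            lns = rng.normal(18.8, 1.9)
            sct = rng.normal(59.4, 13.3)
        else:
            lns = rng.normal(20.2, 2.1)
            sct = rng.normal(81.9, 18.8)

        # raw draws are stored; LOD substitution is the preprocessing
        # stage's job, and the censoring mask records what it must floor
        panel_row = truth.iloc[i]
        censored_row = mask.iloc[i]
        observed = {m: float(panel_row[m]) for m in config.markers}

        subjects.append(SubjectRecord(
            subject_id=sid,
            group=group,
            agent=agent,
            latent_inflammation=latent,
            panss_items=_panss_items(rng, group, latent),
            lns_raw=float(lns),
            sct_raw=float(sct),
            covariates=_covariates(rng, group),
            immune_panel=observed,
            immune_censored={m: bool(censored_row[m]) for m in config.markers},
            hscrp=hscrp,
            qc_fail=i in qc_fail_ids,
        ))

        s_seed = int(np.random.default_rng(
            [config.seed, 7, 0 if config.shared_structure else i]).integers(2**31))
        c_seed = int(np.random.default_rng([config.seed, 11, i]).integers(2**31))
        structure = generate_reward_structure(config.walk, s_seed)
        structures[sid] = structure
        choices[sid] = simulate_agent(structure, agent, c_seed, subject_id=sid)

    return Cohort(config=config, subjects=subjects,
                  structures=structures, choices=choices)
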