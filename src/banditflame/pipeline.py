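"""End-to-end orchestration: simulate -> classify -> preprocess -> stats -> network.

A run is driven by one `RunConfig` (loadable from YAML) and a single seed
that fans out to per-stage child seeds, so every stage is independently
reproducible.  Each stage writes CSV/JSON outputs into the run directory and
a manifest records the config hash, seeds and row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bandit_env import WalkParams
from .synthetic_cohort import Cohort, CohortConfig, generate_cohort
from .explore_classify import (
    classify_trials,
    classify_trials_value_based,
    labels_frame,
    summarize,
)
from .immune_preprocess import PanelTable, apply_lod_rules, hc_anchored_zscores
from .cohort_stats import (
    adjusted_group_test,
    bh_adjust,
    bonferroni_threshold,
    composite_cognitive_score,
    gated_correlation,
    gated_group_test,
    panss_factors,
)
from .network_inference import (
    bootstrap_network,
    centrality,
    estimate_ggm,
    layout_fr,
    select_nodes,
)

__all__ = ["RunConfig", "run_pipeline"]

BEHAVIOR_VARS = ("mean_points", "exploit_mean_run_length", "n_directed", "n_random")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    cohort: CohortConfig | None = None
    scheme: str = "count"  # "count" or "value"
    min_run_len: int = 1
    alpha_select: float = 0.05
    alpha_normality: float = 0.05
    network_gamma: float = 0.5
    bootstrap_B: int = 200
    # replicate fits use a coarser penalty grid than the point estimate;
    # the EBIC optimum is broad, so this barely moves the intervals
    bootstrap_penalties: int = 30
    run_bootstrap: bool = True
    n_top_markers: int = 3  # immune-behavior stage; Bonferroni alpha/m uses this
    out_dir: str = "banditflame_run"

    def __post_init__(self) -> None:
        if self.scheme not in ("count", "value"):
            raise ValueError("scheme must be 'count' or 'value'")
        if self.cohort is None:
            object.__setattr__(self, "cohort",
                               CohortConfig(seed=self.seed))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", None)
        walk_raw = (cohort_raw or {}).pop("walk", None) if cohort_raw else None
        cohort = None
        if cohort_raw is not None:
            if walk_raw is not None:
                cohort_raw["walk"] = WalkParams(**walk_raw)
            cohort = CohortConfig(**cohort_raw)
        cfg = cls(cohort=cohort, **raw)
        return cfg

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _behavior_table(cohort: Cohort, scheme: str, min_run_len: int) -> pd.DataFrame:
    classify = classify_trials if scheme == "count" else classify_trials_value_based
    rows = []
    label_frames = []
    for s in cohort.subjects:
        seq = cohort.choices[s.subject_id]
        labels = classify(seq, cohort.structures[s.subject_id])
        m = summarize(labels, seq, min_run_len=min_run_len)
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "mean_points": m.mean_points,
            "exploit_mean_run_length": m.exploit_mean_run_length,
            "n_directed": m.n_directed,
            "n_random": m.n_random,
            "n_shifts": m.n_shifts,
        }
        row.update({f"nonbest_run_{k}": v
                    for k, v in m.nonbest_mean_run_length_per_arm_rank.items()})
        rows.append(row)
        label_frames.append(labels_frame(labels, seq))
    return (pd.DataFrame(rows).set_index("subject_id"),
            pd.concat(label_frames, ignore_index=True))


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute all stages; returns the manifest (with in-memory results attached).

    Stage order: cohort generation (includes per-subject bandit sessions),
    trial classification, panel preprocessing, group statistics, network
    analysis, and immune-behavior correlations within the patient group
    at the Bonferroni-corrected threshold.
    """
    if config.cohort.n_sz < 3 or config.cohort.n_hc < 3:
        raise ValueError("cohort must have at least 3 subjects per group")
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    results: dict = {}

    # stage 1: cohort + bandit sessions ------------------------------------
    cohort = generate_cohort(config.cohort)
    cohort_df = cohort.to_frame()
    results["cohort"] = cohort
    manifest["stages"]["cohort"] = {"n_subjects": len(cohort.subjects)}

    # stage 2: classification ----------------------------------------------
    behavior, labels_long = _behavior_table(cohort, config.scheme, config.min_run_len)
    results["behavior"] = behavior
    manifest["stages"]["classify"] = {
        "scheme": config.scheme,
        "n_subjects": len(behavior),
        "n_trials_labelled": int(len(labels_long)),
    }

    # stage 3: panel preprocessing -----------------------------------------
    panel = PanelTable(
        values=cohort.panel_frame(),
        below_lod=cohort.censor_frame(),
        lod=pd.Series(cohort.config.lods),
        qc_fail=pd.Series({s.subject_id: s.qc_fail for s in cohort.subjects}),
    )
    cleaned, lod_report = apply_lod_rules(panel)
    groups = cohort.groups().loc[cleaned.values.index]
    zmat = hc_anchored_zscores(cleaned.values, groups)
    results["panel"] = cleaned
    results["zscores"] = zmat
    manifest["stages"]["panel"] = {
        "n_markers_in": len(panel.markers),
        "n_markers_kept": len(cleaned.markers),
        "n_excluded": len(panel.markers) - len(cleaned.markers),
    }

    # stage 4: group statistics --------------------------------------------
    su = cohort_df.loc[cleaned.values.index]
    cognition = composite_cognitive_score(
        cohort_df["lns_raw"], cohort_df["sct_raw"], cohort_df["group"] == "HC")
    cohort_df = cohort_df.assign(cognitive_score=cognition)

    factor_rows = {
        s.subject_id: dataclasses.asdict(panss_factors(s.panss_items))
        for s in cohort.subjects
    }
    factors = pd.DataFrame(factor_rows).T.add_prefix("panss_factor_")

    marker_tests = []
    for m in cleaned.markers:
        r = gated_group_test(cleaned.values[m], groups,
                             alpha_normality=config.alpha_normality, variable=m)
        marker_tests.append(r)
    hs = cohort_df.loc[cleaned.values.index]
    marker_tests.append(gated_group_test(
        hs["hscrp"], groups, alpha_normality=config.alpha_normality,
        variable="hscrp"))
    stats_df = pd.DataFrame([dataclasses.asdict(r) for r in marker_tests])
    stats_df["p_bh"] = bh_adjust(stats_df["p_value"].to_numpy())

    adjusted = []
    for r in marker_tests:
        if r.p_value < config.alpha_select:
            vals = (cleaned.values[r.variable] if r.variable in cleaned.markers
                    else hs[r.variable])
            adj = adjusted_group_test(
                vals, groups, hs[["age", "sex", "bmi"]])
            adjusted.append({"variable": r.variable, **adj})
    adjusted_df = pd.DataFrame(adjusted)

    behavior_tests = pd.DataFrame([
        dataclasses.asdict(gated_group_test(
            behavior[v], behavior["group"],
            alpha_normality=config.alpha_normality, variable=v))
        for v in BEHAVIOR_VARS
    ])
    results["marker_tests"] = stats_df
    results["adjusted_tests"] = adjusted_df
    results["behavior_tests"] = behavior_tests
    results["panss_factors"] = factors
    results["cohort_table"] = cohort_df
    manifest["stages"]["stats"] = {
        "n_marker_tests": len(stats_df),
        "n_behavior_tests": len(behavior_tests),
        "n_adjusted": len(adjusted_df),
    }

    # stage 5: network ------------------------------------------------------
    pvals = stats_df.set_index("variable")["p_value"]
    nodes = select_nodes(pvals, alpha=config.alpha_select)
    net_manifest: dict = {"nodes": nodes}
    if len(nodes) > 1:
        node_data = pd.DataFrame(index=cleaned.values.index)
        for v in nodes[:-1]:
            node_data[v] = (cleaned.values[v] if v in cleaned.markers
                            else hs[v])
        node_data["group"] = (groups == "SZ").astype(float)
        net_seed = int(np.random.default_rng([config.seed, 23]).integers(2**31))
        model = estimate_ggm(node_data, gamma=config.network_gamma)
        cent = centrality(model)
        coords = layout_fr(model, seed=net_seed)
        results["network"] = model
        results["centrality"] = cent
        results["layout"] = coords
        net_manifest.update(alpha=model.alpha, ebic=model.ebic,
                            n_edges=int((np.abs(model.weights) > 1e-10).sum() // 2))
        if config.run_bootstrap:
            boot = bootstrap_network(node_data, B=config.bootstrap_B,
                                     seed=net_seed, gamma=config.network_gamma,
                                     n_penalties=config.bootstrap_penalties)
            results["bootstrap"] = boot
            net_manifest["bootstrap_B"] = boot.n_requested
            net_manifest["bootstrap_dropped"] = boot.n_dropped
    manifest["stages"]["network"] = net_manifest

    # stage 6: immune-behavior correlations within the patient group --------
    # top markers = strongest group associations (smallest uncorrected p)
    top = (stats_df.sort_values("p_value")
           .head(config.n_top_markers)["variable"].tolist())
    threshold = bonferroni_threshold(0.05, config.n_top_markers)
    sz_ids = groups.index[groups == "SZ"]
    rows = []
    for m in top:
        mv = (cleaned.values.loc[sz_ids, m] if m in cleaned.markers
              else hs.loc[sz_ids, m])
        for v in ("n_random", "exploit_mean_run_length", "n_directed"):
            bv = behavior.loc[behavior.index.intersection(sz_ids), v]
            mv_al = mv.loc[bv.index]
            r = gated_correlation(mv_al, bv,
                                  alpha_normality=config.alpha_normality,
                                  pair=(m, v))
            rows.append({"marker": m, "behavior": v, "method": r.method,
                         "coefficient": r.coefficient, "p_value": r.p_value,
                         "n": r.n, "significant": r.p_value < threshold})
    corr_df = pd.DataFrame(rows)
    results["immune_behavior"] = corr_df
    manifest["stages"]["immune_behavior"] = {
        "markers": top, "bonferroni_threshold": round(threshold, 3),
        "n_tests": len(corr_df),
    }

    if write:
        cohort_df.to_csv(out / "cohort.csv")
        behavior.to_csv(out / "behavior_metrics.csv")
        labels_long.to_csv(out / "trial_labels.csv", index=False)
        cleaned.values.to_csv(out / "panel_cleaned.csv")
        zmat.values.to_csv(out / "panel_zscores.csv")
        pd.DataFrame(lod_report).to_csv(out / "lod_report.csv", index=False)
        stats_df.to_csv(out / "marker_tests.csv", index=False)
        behavior_tests.to_csv(out / "behavior_tests.csv", index=False)
        if len(adjusted_df):
            adjusted_df.to_csv(out / "adjusted_tests.csv", index=False)
        factors.to_csv(out / "panss_factors.csv")
        corr_df.to_csv(out / "immune_behavior.csv", index=False)
        if "network" in results:
            results["network"].edge_frame().to_csv(out / "network_edges.csv", index=False)
            results["centrality"].to_frame().to_csv(out / "network_centrality.csv")
            results["layout"].to_csv(out / "network_layout.csv")
            if "bootstrap" in results:
                results["bootstrap"].edge_ci_frame().to_csv(
                    out / "network_edge_cis.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    manifest["results"] = results
    return manifest
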