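"""Immune-panel cleaning: QC flags, limit-of-detection rules, HC-anchored z-scores.

Multiplex protein panels report log2 expression values with an assay-specific
limit of detection (LOD).  Cleaning follows two rules applied in order:

1. a marker whose below-LOD fraction exceeds the exclusion threshold
   (strictly more than 80% by default) is dropped from the panel;
2. remaining below-LOD cells are substituted with the marker's LOD.

Exclusion fractions are computed on the raw censoring mask after removing
QC-failed subjects, before any substitution.  Standardization for heatmaps
anchors every marker to the healthy-control group:
z = (value - mean_HC) / sd_HC, with the sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PanelTable", "ZScoreMatrix", "apply_lod_rules", "hc_anchored_zscores"]


@dataclass
class PanelTable:
    """Subjects x markers log2 panel with censoring metadata."""

    values: pd.DataFrame  # subjects x markers
    below_lod: pd.DataFrame  # same shape, bool
    lod: pd.Series  # per marker
    qc_fail: pd.Series | None = None  # per subject, bool
    exclusions: dict = field(default_factory=dict)  # marker -> reason

    def __post_init__(self) -> None:
        if self.values.shape != self.below_lod.shape:
            raise ValueError("values and below_lod must share shape")
        missing = [m for m in self.values.columns if m not in self.lod.index]
        if missing:
            raise ValueError(f"missing LOD for markers: {missing}")
        if self.qc_fail is None:
            self.qc_fail = pd.Series(False, index=self.values.index)

    @property
    def markers(self) -> list:
        return list(self.values.columns)

    def passing_subjects(self) -> pd.Index:
        return self.values.index[~self.qc_fail.loc[self.values.index]]


@dataclass(frozen=True)
class ZScoreMatrix:
    """Panel standardized against the reference (HC) group per marker."""

    values: pd.DataFrame
    reference_group: str
    undefined_markers: tuple = ()


def apply_lod_rules(
    panel: PanelTable, exclusion_threshold: float = 0.80
) -> tuple[PanelTable, list]:
    """Drop markers with >threshold below-LOD fraction, floor the rest at LOD.

    Returns the cleaned panel (QC-failed subjects removed) and an exclusion
    report: one record per marker with its below-LOD fraction and the action
    taken.  The exclusion decision uses the raw mask; substitution happens
    after, so applying the rules twice is a no-op.
    """
    keep_subjects = panel.passing_subjects()
    values = panel.values.loc[keep_subjects]
    mask = panel.below_lod.loc[keep_subjects]

    report = []
    kept, excluded = [], {}
    for m in panel.markers:
        frac = float(mask[m].mean())
        action = "excluded" if frac > exclusion_threshold else "retained"
        report.append({"marker": m, "fraction_below_lod": frac, "action": action})
        if action == "excluded":
            excluded[m] = f">{exclusion_threshold:.0%} of values below LOD"
        else:
            kept.append(m)

    cleaned = values[kept].copy()
    for m in kept:
        cleaned.loc[mask[m], m] = panel.lod[m]

    out = PanelTable(
        values=cleaned,
        below_lod=mask[kept].copy(),
        lod=panel.lod[kept],
        qc_fail=pd.Series(False, index=keep_subjects),
        exclusions={**panel.exclusions, **excluded},
    )
    return out, report


def hc_anchored_zscores(
    panel: pd.DataFrame, groups: pd.Series, reference: str = "HC"
) -> ZScoreMatrix:
    """Standardize every marker against the reference group's mean and SD.

    The reference columns come out with mean exactly 0 and sd exactly 1.
    Markers with zero reference variance are flagged and returned as NaN.
    """
    groups = groups.loc[panel.index]
    ref = panel.loc[groups == reference]
    if len(ref) < 2:
        raise ValueError(f"need >=2 {reference} subjects to anchor z-scores")
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    undefined = tuple(sd.index[(sd == 0) | sd.isna()])
    sd_safe = sd.replace(0, np.nan)
    z = (panel - mean) / sd_safe
    return ZScoreMatrix(values=z, reference_group=reference,
                        undefined_markers=undefined)
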