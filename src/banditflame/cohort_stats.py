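"""Normality-gated group tests and correlations, effect sizes, covariate
adjustment, multiplicity control, PANSS factor scoring, and the composite
cognitive score.

The gating convention: every variable is screened with the Shapiro-Wilk test
(per group for group comparisons, per variable for correlations).  Normal
data get a two-sided Student's t test / Pearson correlation; otherwise a
Mann-Whitney U test / Spearman correlation is used.  Cohen's d (pooled-SD
standardized mean difference) is reported in both branches so effect sizes
stay comparable across the gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "GatedTestResult",
    "GatedCorrelationResult",
    "PanssFactors",
    "cohens_d",
    "gated_group_test",
    "gated_correlation",
    "partial_correlation",
    "bh_adjust",
    "bonferroni_threshold",
    "adjusted_group_test",
    "panss_factors",
    "composite_cognitive_score",
]

PANSS_FACTORS = {
    "negative": ("N1", "N2", "N3", "N4", "N6", "G7"),
    "positive": ("P1", "P3", "P5", "G9"),
    "disorganized": ("P2", "N5", "G11"),
    "depressive": ("P4", "P7", "G8", "G14"),
}


@dataclass(frozen=True)
class GatedTestResult:
    variable: str
    test_used: str  # "t" or "mann_whitney"
    statistic: float
    p_value: float
    cohens_d: float
    normal_a: bool
    normal_b: bool
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class GatedCorrelationResult:
    pair: tuple
    method: str  # "pearson" or "spearman"
    coefficient: float
    p_value: float
    n: int


@dataclass(frozen=True)
class PanssFactors:
    negative: int
    positive: int
    disorganized: int
    depressive: int

    def __post_init__(self) -> None:
        bounds = {"negative": (6, 42), "positive": (4, 28),
                  "disorganized": (3, 21), "depressive": (4, 28)}
        for name, (lo, hi) in bounds.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name} factor {v} outside [{lo}, {hi}]")


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD standardized mean difference (a minus b)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue >= alpha


def gated_group_test(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    alpha_normality: float = 0.05,
    variable: str = "",
) -> GatedTestResult:
    """Shapiro-Wilk-gated two-group comparison.

    Both groups normal -> two-sided Student's t; otherwise Mann-Whitney U.
    The first group label in sorted order is group A (HC before SZ).
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 subjects per group")
    if np.ptp(values) == 0:
        raise ValueError(f"variable {variable!r} is constant")

    normal_a = _is_normal(a, alpha_normality)
    normal_b = _is_normal(b, alpha_normality)
    if normal_a and normal_b:
        res = stats.ttest_ind(a, b)
        used = "t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        used = "mann_whitney"
    return GatedTestResult(
        variable=variable, test_used=used,
        statistic=float(res.statistic), p_value=float(res.pvalue),
        cohens_d=cohens_d(a, b), normal_a=normal_a, normal_b=normal_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        n_a=len(a), n_b=len(b),
    )


def gated_correlation(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    alpha_normality: float = 0.05,
    pair: tuple = ("x", "y"),
) -> GatedCorrelationResult:
    """Pearson when both marginals pass Shapiro-Wilk, else Spearman."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input")
    if _is_normal(x, alpha_normality) and _is_normal(y, alpha_normality):
        r, p = stats.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = stats.spearmanr(x, y)
        method = "spearman"
    return GatedCorrelationResult(pair=pair, method=method,
                                  coefficient=float(r), p_value=float(p),
                                  n=len(x))


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), z])
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None = None,
    method: str = "pearson",
) -> GatedCorrelationResult:
    """Correlation of x and y after projecting out the covariates.

    Both x and y are residualized against the covariate matrix (plus an
    intercept) and the residuals are correlated with Pearson.  For
    ``method="spearman"`` all variables are rank-transformed first.  With no
    covariates this reduces exactly to the plain correlation.  The p value
    uses the t distribution with n - k - 2 degrees of freedom, k the number
    of covariates.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if covariates is None or (hasattr(covariates, "shape") and np.size(covariates) == 0):
        z = np.empty((len(x), 0))
    else:
        z = np.asarray(covariates, float)
        if z.ndim == 1:
            z = z[:, None]
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z).all(axis=1)
    x, y, z = x[ok], y[ok], z[ok]
    n, k = len(x), z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2 complete observations")
    if k:
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), z]))
        if rank < k + 1:
            raise ValueError("covariate matrix is rank deficient (collinear columns)")

    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
        z = np.apply_along_axis(stats.rankdata, 0, z) if k else z
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    rx = _residualize(x, z)
    ry = _residualize(y, z)
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(tstat), dof))
    return GatedCorrelationResult(pair=("x", "y"), method=f"partial_{method}",
                                  coefficient=r, p_value=p, n=n)


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m (display at 3 decimals)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def adjusted_group_test(
    marker: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> dict:
    """Group effect from a general linear model marker ~ group + covariates.

    Returns the two-sided p value and coefficient for the group term.
    Categorical covariate columns (e.g. sex) are dummy-coded.
    """
    y = np.asarray(marker, float)
    g = pd.Series(np.asarray(groups))
    labels = sorted(g.unique())
    if len(labels) != 2:
        raise ValueError("expected exactly 2 groups")
    gcode = (g == labels[1]).astype(float).to_numpy()

    if covariates is None:
        X = pd.DataFrame({"group": gcode})
    else:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        cov = pd.get_dummies(cov, drop_first=True, dtype=float)
        X = pd.concat([pd.Series(gcode, name="group"), cov], axis=1)
    X = sm.add_constant(X.astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(y, X).fit()
    return {
        "coef": float(fit.params["group"]),
        "p_value": float(fit.pvalues["group"]),
        "higher_group": labels[1] if fit.params["group"] > 0 else labels[0],
        "n": int(fit.nobs),
    }


def panss_factors(items: dict | pd.Series) -> PanssFactors:
    """Five-factor PANSS scoring (negative/positive/disorganized/depressive sums)."""
    items = dict(items)
    sums = {}
    for factor, members in PANSS_FACTORS.items():
        vals = []
        for it in members:
            v = int(items[it])
            if not (1 <= v <= 7):
                raise ValueError(f"PANSS item {it} = {v} outside [1, 7]")
            vals.append(v)
        sums[factor] = int(sum(vals))
    return PanssFactors(**sums)


def composite_cognitive_score(
    lns: np.ndarray | pd.Series,
    sct: np.ndarray | pd.Series,
    hc_mask: np.ndarray | pd.Series,
) -> np.ndarray:
    """Mean of the two subtest z-scores, each anchored to the HC group.

    By construction the HC mean of the composite is exactly 0.
    """
    lns = np.asarray(lns, float)
    sct = np.asarray(sct, float)
    hc = np.asarray(hc_mask, bool)
    if hc.sum() < 2:
        raise ValueError("need at least 2 HC subjects")
    zs = []
    for test in (lns, sct):
        mu = test[hc].mean()
        sd = test[hc].std(ddof=1)
        if sd == 0:
            raise ValueError("zero HC variance in a subtest")
        zs.append((test - mu) / sd)
    return (zs[0] + zs[1]) / 2.0
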