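"""Gaussian-graphical-model network analysis of immune markers and group.

Four steps mirror the psychometric-network workflow:

1. node selection -- markers whose uncorrected group-difference p value is
   below 0.05, plus a binary group-affiliation node;
2. GGM estimation -- graphical lasso over a log-spaced penalty grid, model
   chosen by the extended BIC (EBIC); edges are the partial correlations
   implied by the selected precision matrix,
   pcor_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj);
3. characterization -- strength, closeness and betweenness centrality on
   the weighted graph (path lengths use distance 1/|weight|);
4. accuracy -- nonparametric bootstrap over subjects: percentile confidence
   intervals for every edge and difference tests for edges and centralities.

The binary group node is entered as a 0/1 column and correlated with
Pearson (point-biserial) for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.covariance import graphical_lasso

__all__ = [
    "NetworkModel",
    "CentralityReport",
    "BootstrapReport",
    "select_nodes",
    "sample_partial_correlations",
    "estimate_ggm",
    "centrality",
    "bootstrap_network",
    "layout_fr",
]


@dataclass(frozen=True)
class NetworkModel:
    """Estimated GGM: node names and the symmetric partial-correlation matrix."""

    nodes: tuple
    weights: np.ndarray  # (p, p), symmetric, zero diagonal
    alpha: float  # selected graphical-lasso penalty (0 = unregularized)
    ebic: float
    gamma: float = 0.5

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node count")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if np.abs(np.diag(w)).max() > 1e-12:
            raise ValueError("weight diagonal must be zero")
        if np.abs(w).max() > 1.0 + 1e-9:
            raise ValueError("partial correlations must lie in [-1, 1]")

    def edge_frame(self) -> pd.DataFrame:
        rows = []
        p = len(self.nodes)
        for i in range(p):
            for j in range(i + 1, p):
                rows.append({"node_i": self.nodes[i], "node_j": self.nodes[j],
                             "weight": self.weights[i, j]})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CentralityReport:
    nodes: tuple
    strength: np.ndarray
    closeness: np.ndarray
    betweenness: np.ndarray
    disconnected: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": self.nodes, "strength": self.strength,
             "closeness": self.closeness, "betweenness": self.betweenness}
        ).set_index("node")


@dataclass(frozen=True)
class BootstrapReport:
    nodes: tuple
    point_weights: np.ndarray  # (p, p)
    boot_weights: np.ndarray  # (B_kept, p, p)
    boot_strength: np.ndarray  # (B_kept, p)
    ci_low: np.ndarray  # (p, p)
    ci_high: np.ndarray  # (p, p)
    n_requested: int
    n_dropped: int
    level: float = 0.95

    def edge_ci_frame(self) -> pd.DataFrame:
        rows = []
        p = len(self.nodes)
        for i in range(p):
            for j in range(i + 1, p):
                rows.append({
                    "node_i": self.nodes[i], "node_j": self.nodes[j],
                    "weight": self.point_weights[i, j],
                    "ci_low": self.ci_low[i, j], "ci_high": self.ci_high[i, j],
                })
        return pd.DataFrame(rows)

    def edges_differ(self, edge_a: tuple, edge_b: tuple) -> bool:
        """True when the bootstrap CI of the edge-weight difference excludes 0."""
        ia, ja = (self.nodes.index(edge_a[0]), self.nodes.index(edge_a[1]))
        ib, jb = (self.nodes.index(edge_b[0]), self.nodes.index(edge_b[1]))
        diff = self.boot_weights[:, ia, ja] - self.boot_weights[:, ib, jb]
        lo, hi = np.quantile(diff, [(1 - self.level) / 2, (1 + self.level) / 2])
        return bool(lo > 0 or hi < 0)

    def strengths_differ(self, node_a: str, node_b: str) -> bool:
        """True when the bootstrap CI of the strength difference excludes 0."""
        ia, ib = self.nodes.index(node_a), self.nodes.index(node_b)
        diff = self.boot_strength[:, ia] - self.boot_strength[:, ib]
        lo, hi = np.quantile(diff, [(1 - self.level) / 2, (1 + self.level) / 2])
        return bool(lo > 0 or hi < 0)


def select_nodes(p_values: dict | pd.Series, alpha: float = 0.05,
                 group_node: str = "group") -> list:
    """Markers with uncorrected p < alpha, plus the group-affiliation node.

    Returns just [group_node] (with a warning) when nothing passes.
    """
    p = pd.Series(p_values)
    selected = [str(m) for m in p.index[p < alpha]]
    if not selected:
        warnings.warn("no marker passed the selection threshold; "
                      "network estimation skipped", UserWarning, stacklevel=2)
    return selected + [group_node]


def _pcor_from_precision(omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return (pcor + pcor.T) / 2.0


def sample_partial_correlations(data: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Unregularized partial correlations from the inverse sample covariance."""
    x = np.asarray(data, float)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(
            f"need n > p + 1 subjects for an invertible covariance (n={n}, p={p}); "
            "use estimate_ggm for the regularized path")
    cov = np.cov(x, rowvar=False)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular sample covariance; use the regularized path")
    return _pcor_from_precision(np.linalg.inv(cov))


def _ebic(precision: np.ndarray, emp_cov: np.ndarray, n: int, gamma: float) -> float:
    p = precision.shape[0]
    sign, logdet = np.linalg.slogdet(precision)
    loglik = (n / 2.0) * (logdet - np.trace(emp_cov @ precision))
    nonzero = np.abs(precision[np.triu_indices(p, 1)]) > 1e-10
    E = int(nonzero.sum())
    return float(-2.0 * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def estimate_ggm(
    data: pd.DataFrame,
    gamma: float = 0.5,
    n_penalties: int = 100,
    penalty_min_ratio: float = 0.01,
    alpha: float | None = None,
) -> NetworkModel:
    """EBIC-selected graphical-lasso GGM on standardized columns.

    The penalty grid runs log-spaced from lambda_max (the smallest penalty
    that zeroes every edge, i.e. the largest absolute off-diagonal
    correlation) down to ``penalty_min_ratio * lambda_max``.  Passing
    ``alpha=0`` forces the unregularized model and reproduces
    ``sample_partial_correlations`` exactly.
    """
    nodes = tuple(str(c) for c in data.columns)
    x = np.asarray(data, float)
    n, p = x.shape
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = [nodes[i] for i in np.where(sd == 0)[0]]
        raise ValueError(f"constant columns cannot enter the network: {bad}")
    xs = (x - x.mean(axis=0)) / sd
    emp_cov = np.corrcoef(x, rowvar=False)

    if alpha is not None:
        if alpha == 0:
            pcor = sample_partial_correlations(xs)
            prec = np.linalg.inv(np.cov(xs, rowvar=False))
            return NetworkModel(nodes=nodes, weights=pcor, alpha=0.0,
                                ebic=_ebic(prec, emp_cov, n, gamma), gamma=gamma)
        grid = [float(alpha)]
    else:
        lam_max = np.abs(emp_cov - np.eye(p)).max()
        if lam_max <= 0:
            lam_max = 1e-3
        grid = list(np.geomspace(lam_max, lam_max * penalty_min_ratio,
                                 num=n_penalties))

    best = None
    failures = []
    for lam in grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, prec = graphical_lasso(emp_cov, alpha=lam, max_iter=200)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            failures.append((lam, str(exc)))
            continue
        score = _ebic(prec, emp_cov, n, gamma)
        if best is None or score < best[0]:
            best = (score, lam, prec)
    if best is None:
        raise RuntimeError(
            "graphical lasso failed to converge on the whole penalty grid; "
            f"first failures: {failures[:3]}")
    score, lam, prec = best
    return NetworkModel(nodes=nodes, weights=_pcor_from_precision(prec),
                        alpha=float(lam), ebic=score, gamma=gamma)


def _graph(model: NetworkModel, eps: float = 1e-10) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(model.nodes)
    p = len(model.nodes)
    for i in range(p):
        for j in range(i + 1, p):
            w = model.weights[i, j]
            if abs(w) > eps:
                g.add_edge(model.nodes[i], model.nodes[j],
                           weight=abs(w), signed_weight=w,
                           distance=1.0 / abs(w))
    return g


def centrality(model: NetworkModel) -> CentralityReport:
    """Strength, closeness, betweenness on the absolute-weight graph.

    Closeness and betweenness use shortest paths with edge length
    1/|weight|; in a disconnected graph closeness is computed within each
    node's component (harmonic-free Wasserman-Faust-style normalization is
    not applied) and the report is flagged.
    """
    g = _graph(model)
    strength = np.array([sum(abs(model.weights[i])) for i in range(len(model.nodes))])
    clo = nx.closeness_centrality(g, distance="distance")
    bet = nx.betweenness_centrality(g, weight="distance", normalized=False)
    disconnected = nx.number_connected_components(g) > 1
    return CentralityReport(
        nodes=model.nodes,
        strength=strength,
        closeness=np.array([clo[v] for v in model.nodes]),
        betweenness=np.array([bet[v] for v in model.nodes]),
        disconnected=disconnected,
    )


def bootstrap_network(
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    gamma: float = 0.5,
    level: float = 0.95,
    n_penalties: int = 100,
) -> BootstrapReport:
    """Nonparametric (subject-resampling) bootstrap of the GGM.

    Each replicate re-estimates the full EBIC-glasso path.  Replicates whose
    resample has a constant column or fails to converge are dropped and
    counted; more than 5% drops is an error.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for percentile intervals")
    point = estimate_ggm(data, gamma=gamma, n_penalties=n_penalties)
    n = len(data)
    p = len(point.nodes)
    rng = np.random.default_rng(seed)

    boots = []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx]
        try:
            m = estimate_ggm(sample, gamma=gamma, n_penalties=n_penalties)
        except (ValueError, RuntimeError):
            dropped += 1
            continue
        boots.append(m.weights)
    if dropped > 0.05 * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap replicates failed")

    bw = np.stack(boots)
    lo_q, hi_q = (1 - level) / 2, (1 + level) / 2
    ci_low = np.quantile(bw, lo_q, axis=0)
    ci_high = np.quantile(bw, hi_q, axis=0)
    strength = np.abs(bw).sum(axis=2)
    return BootstrapReport(
        nodes=point.nodes, point_weights=point.weights, boot_weights=bw,
        boot_strength=strength, ci_low=ci_low, ci_high=ci_high,
        n_requested=B, n_dropped=dropped, level=level,
    )


def layout_fr(model: NetworkModel, seed: int = 0) -> pd.DataFrame:
    """Fruchterman-Reingold node coordinates (deterministic under seed)."""
    if len(model.nodes) < 2:
        raise ValueError("need at least 2 nodes to lay out")
    g = _graph(model)
    pos = nx.spring_layout(g, weight="weight", seed=seed)
    return pd.DataFrame(
        [{"node": v, "x": xy[0], "y": xy[1]} for v, xy in pos.items()]
    ).set_index("node")
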