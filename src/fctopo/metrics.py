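"""Global and nodal graph metrics and their AUC summaries.

All metrics operate on undirected binary graphs.  Conventions for
degenerate cases follow the standard graph-theory resolutions:

* clustering and local efficiency of a node with degree < 2 are 0, and such
  nodes are included in network means (the means divide by N, not by the
  count of eligible nodes);
* path-type averages (characteristic path length, nodal path length) run
  over *reachable* pairs only, with isolated nodes marked NaN;
* efficiency-type metrics use the 1/infinity = 0 convention for
  unreachable pairs, so they are defined on disconnected graphs.

A metric measured at every sparsity of a sweep forms a curve; the
trapezoidal area under that curve (AUC) is the threshold-free summary that
downstream group statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path
from sklearn.base import BaseEstimator, TransformerMixin

from .graph import BinaryGraph, SparsitySweep

GLOBAL = "GLOBAL"

#: nodal metrics emitted by sweep_metrics, in output order
NODAL_METRICS = (
    "degree",
    "clustering",
    "local_efficiency",
    "nodal_path_length",
    "nodal_efficiency",
    "betweenness",
)
#: global metrics emitted by sweep_metrics
GLOBAL_METRICS = (
    "clustering",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
)


def _adj(g: BinaryGraph | np.ndarray) -> np.ndarray:
    return g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)


def nodal_degree(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """k_i = sum_j A_ij: number of direct connections of each node."""
    return _adj(g).sum(axis=1).astype(int)


def triangle_counts(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """T_i: number of triangles through each node (diag(A^3)/2)."""
    a = _adj(g).astype(np.int64)
    return np.diag(a @ a @ a) // 2


def clustering_coefficient(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """Per-node clustering C_i = 2 T_i / (k_i (k_i - 1)); 0 where k_i < 2."""
    k = nodal_degree(g).astype(float)
    t = triangle_counts(g).astype(float)
    c = np.zeros_like(k)
    ok = k >= 2
    c[ok] = 2.0 * t[ok] / (k[ok] * (k[ok] - 1.0))
    return c


def mean_clustering(g: BinaryGraph | np.ndarray) -> float:
    """Network clustering coefficient C = (1/N) sum_i C_i."""
    return float(clustering_coefficient(g).mean())


def shortest_path_lengths(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths d_ij; unreachable pairs are +inf."""
    a = _adj(g)
    return _csgraph_shortest_path(csr_matrix(a), method="D", unweighted=True)


def characteristic_path_length(g: BinaryGraph | np.ndarray,
                               d: np.ndarray | None = None) -> float:
    """Mean shortest path length over reachable ordered pairs i != j."""
    if d is None:
        d = shortest_path_lengths(g)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        raise ValueError("no reachable node pair: path length undefined")
    return float(d[finite].mean())


def global_efficiency(g: BinaryGraph | np.ndarray,
                      d: np.ndarray | None = None) -> float:
    """E_glob = (1/(N(N-1))) sum_{i != j} 1/d_ij, with 1/inf = 0."""
    if d is None:
        d = shortest_path_lengths(g)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d == 0, np.inf, d), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def local_efficiency(g: BinaryGraph | np.ndarray) -> np.ndarray:
    """E_loc(i): global efficiency of the subgraph induced on i's neighbors."""
    a = _adj(g)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        out[i] = global_efficiency(a[np.ix_(nb, nb)])
    return out


def mean_local_efficiency(g: BinaryGraph | np.ndarray) -> float:
    """E_loc = (1/N) sum_i E_glob(G_i)."""
    return float(local_efficiency(g).mean())


def nodal_path_length(g: BinaryGraph | np.ndarray,
                      d: np.ndarray | None = None) -> np.ndarray:
    """Mean shortest path from node i to the nodes it can reach; NaN if none."""
    if d is None:
        d = shortest_path_lengths(g)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    counts = finite.sum(axis=1)
    sums = np.where(finite, d, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def nodal_efficiency(g: BinaryGraph | np.ndarray,
                     d: np.ndarray | None = None) -> np.ndarray:
    """E_nodal(i) = (1/(N-1)) sum_{j != i} 1/d_ij; node mean equals E_glob."""
    if d is None:
        d = shortest_path_lengths(g)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d == 0, np.inf, d), 0.0)
    return inv.sum(axis=1) / (n - 1)


def betweenness_centrality(g: BinaryGraph | np.ndarray,
                           normalized: bool = False) -> np.ndarray:
    """Shortest-path betweenness (Brandes accumulation), unnormalized.

    Each unordered pair (s, t) distributes one unit of credit across its
    shortest paths, split fractionally among equal-length alternatives.
    With ``normalized=True`` values are divided by (N-1)(N-2)/2.
    """
    a = _adj(g)
    n = a.shape[0]
    neighbors = [np.flatnonzero(a[i]) for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        # single-source BFS recording predecessors and path counts
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        queue = [s]
        while queue:
            v = queue.pop(0)
            order.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # undirected: each pair visited from both endpoints
    if normalized and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    return bc


@dataclass
class MetricCurve:
    """One metric's values across the sparsity sweep (one node, or GLOBAL)."""

    metric_name: str
    node: str
    sparsities: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sparsities = np.asarray(self.sparsities, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sparsities.shape != self.values.shape:
            raise ValueError("sparsities and values must align")
        if np.any(np.diff(self.sparsities) <= 0):
            raise ValueError("sparsities must be strictly increasing")


@dataclass
class AUCSummary:
    metric_name: str
    node: str
    auc: float


def auc_over_sparsity(curve: MetricCurve) -> AUCSummary:
    """Trapezoidal area of a metric curve over the sparsity axis.

    Points whose value is undefined (NaN) are dropped pairwise before
    integration; at least two finite points are required.
    """
    ok = np.isfinite(curve.values)
    s, v = curve.sparsities[ok], curve.values[ok]
    if s.size < 2:
        raise ValueError(
            f"curve {curve.metric_name}/{curve.node}: need >= 2 finite points for an area"
        )
    return AUCSummary(curve.metric_name, curve.node,
                      float(np.trapezoid(v, s)))


def graph_metric_table(g: BinaryGraph, node_names: list[str] | None = None) -> pd.DataFrame:
    """Long-format table (metric, node, value) of every metric on one graph."""
    n = g.n_nodes
    if node_names is None:
        node_names = [f"R{i + 1}" for i in range(n)]
    d = shortest_path_lengths(g)
    rows: list[tuple[str, str, float]] = []
    nodal_values = {
        "degree": nodal_degree(g).astype(float),
        "clustering": clustering_coefficient(g),
        "local_efficiency": local_efficiency(g),
        "nodal_path_length": nodal_path_length(g, d),
        "nodal_efficiency": nodal_efficiency(g, d),
        "betweenness": betweenness_centrality(g),
    }
    for name in NODAL_METRICS:
        for i, v in enumerate(nodal_values[name]):
            rows.append((name, node_names[i], float(v)))
    try:
        cpl = characteristic_path_length(g, d)
    except ValueError:
        cpl = float("nan")
    global_values = {
        "clustering": float(nodal_values["clustering"].mean()),
        "characteristic_path_length": cpl,
        "global_efficiency": global_efficiency(g, d),
        "local_efficiency": float(nodal_values["local_efficiency"].mean()),
    }
    for name in GLOBAL_METRICS:
        rows.append((name, GLOBAL, global_values[name]))
    return pd.DataFrame(rows, columns=["metric", "node", "value"])


def sweep_metrics(sweep: SparsitySweep, node_names: list[str] | None = None,
                  subject_id: str = "") -> pd.DataFrame:
    """Metric table for every graph in a sweep: (subject, sparsity, metric, node, value)."""
    frames = []
    for s, g in zip(sweep.sparsities, sweep.graphs):
        t = graph_metric_table(g, node_names)
        t.insert(0, "sparsity", float(s))
        frames.append(t)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject", subject_id)
    return out


def auc_table(metric_long: pd.DataFrame) -> pd.DataFrame:
    """AUC per (subject, metric, node) from a long sweep-metric table."""
    rows = []
    for (subj, metric, node), grp in metric_long.groupby(
            ["subject", "metric", "node"], sort=False):
        grp = grp.sort_values("sparsity")
        curve = MetricCurve(metric, node, grp["sparsity"].to_numpy(),
                            grp["value"].to_numpy())
        try:
            rows.append((subj, metric, node, auc_over_sparsity(curve).auc))
        except ValueError:
            rows.append((subj, metric, node, float("nan")))
    return pd.DataFrame(rows, columns=["subject", "metric", "node", "auc"])


class GraphMetricsAUC(BaseEstimator, TransformerMixin):
    """Transformer from per-subject sparsity sweeps to AUC feature tables.

    ``transform`` returns a wide DataFrame with one row per subject and one
    ``metric|node`` column per (metric, node) pair — the feature matrix the
    group tests consume.

    Attributes
    ----------
    node_names_ : list of str
        Node labels applied to every subject's graphs.
    """

    def __init__(self, node_names: list[str] | None = None):
        self.node_names = node_names

    def fit(self, X: list[SparsitySweep], y=None) -> "GraphMetricsAUC":
        if len(X) == 0:
            raise ValueError("no sweeps given")
        n = X[0].graphs[0].n_nodes
        self.node_names_ = (list(self.node_names) if self.node_names is not None
                            else [f"R{i + 1}" for i in range(n)])
        return self

    def transform(self, X: list[SparsitySweep]) -> pd.DataFrame:
        long = pd.concat(
            [sweep_metrics(sw, self.node_names_, subject_id=str(i))
             for i, sw in enumerate(X)], ignore_index=True)
        aucs = auc_table(long)
        wide = aucs.pivot_table(index="subject",
                                columns=["metric", "node"], values="auc",
                                sort=False)
        wide.columns = [f"{m}|{n}" for m, n in wide.columns]
        wide.index = wide.index.astype(int)
        return wide.sort_index()
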