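"""Random-network null models and nodal small-world propensity.

A node shows small-world character when its local clustering is high and
its path lengths are short relative to a random network with the same
number of nodes and edges.  The nodal index computed here is the product

    gamma_i = (C_obs(i) / C_null(i)) * (L_obs(i) / L_null(i)),

where the null values are ensemble means over random realizations.  Note
that, as a product, longer-than-random paths *increase* gamma_i; the
classical small-worldness ratio sigma_i = (C_obs/C_null) / (L_obs/L_null)
is therefore computed alongside and both are reported.

Two null models are available: degree-preserving rewiring (Maslov–Sneppen
double-edge swaps, the field standard — preserves each node's degree
exactly) and Erdos–Renyi G(n, m) (preserves only node and edge counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .graph import BinaryGraph
from .metrics import clustering_coefficient, nodal_path_length


@dataclass
class NullEnsemble:
    """Random graphs matched to a source graph's size."""

    realizations: list[BinaryGraph]
    model: str
    seed: int | None = None

    @property
    def n_realizations(self) -> int:
        return len(self.realizations)


@dataclass
class SWPResult:
    """Per-node small-world propensity and its two factors."""

    gamma: np.ndarray          # C_ratio * L_ratio (as printed)
    sigma: np.ndarray          # C_ratio / L_ratio (classical index)
    c_ratio: np.ndarray
    l_ratio: np.ndarray
    c_null_mean: np.ndarray
    l_null_mean: np.ndarray


def _degree_preserving_rewire(a: np.ndarray, rng: np.random.Generator,
                              swaps_per_edge: int) -> tuple[np.ndarray, int]:
    """Maslov–Sneppen double-edge swaps; returns (rewired adjacency, n accepted).

    Attempts ``swaps_per_edge * m`` swaps; proposals creating self-loops or
    multi-edges are rejected.  Degree sequence is preserved exactly.
    """
    a = a.copy()
    iu, ju = np.nonzero(np.triu(a, k=1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    m = len(edges)
    accepted = 0
    n_attempts = swaps_per_edge * m
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        u, v = edges[e1]
        x, y = edges[e2]
        if rng.random() < 0.5:
            x, y = y, x
        # propose (u,v),(x,y) -> (u,x),(v,y)
        if u == x or v == y:
            continue
        if a[u, x] or a[v, y]:
            continue
        a[u, v] = a[v, u] = 0
        a[x, y] = a[y, x] = 0
        a[u, x] = a[x, u] = 1
        a[v, y] = a[y, v] = 1
        edges[e1] = (min(u, x), max(u, x))
        edges[e2] = (min(v, y), max(v, y))
        accepted += 1
    return a, accepted


def _gnm_random(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform G(n, m): m distinct node pairs chosen without replacement."""
    iu, ju = np.triu_indices(n, k=1)
    pick = rng.choice(iu.size, size=m, replace=False)
    a = np.zeros((n, n), dtype=np.uint8)
    a[iu[pick], ju[pick]] = 1
    return a | a.T


def generate_null(g: BinaryGraph, model: str = "degree_preserving",
                  n_realizations: int = 100,
                  seed: int | np.random.SeedSequence | None = None,
                  swaps_per_edge: int = 10) -> NullEnsemble:
    """Ensemble of random graphs with the source graph's N and edge count.

    ``degree_preserving`` additionally keeps every node's degree.  If a
    graph admits no valid swap at all (e.g. a star), a warning is issued and
    the realizations equal the source graph.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    if model not in ("degree_preserving", "erdos_renyi_gnm"):
        raise ValueError(f"unknown null model {model!r}")
    rng = np.random.default_rng(seed)
    a0 = g.adjacency
    n, m = g.n_nodes, g.n_edges
    if m < 1:
        raise ValueError("cannot build a null ensemble for an edgeless graph")
    realizations = []
    total_accepted = 0
    for _ in range(n_realizations):
        if model == "degree_preserving":
            a, acc = _degree_preserving_rewire(a0, rng, swaps_per_edge)
            total_accepted += acc
        else:
            a = _gnm_random(n, m, rng)
        realizations.append(BinaryGraph(adjacency=a, sparsity=g.sparsity))
    if model == "degree_preserving" and total_accepted == 0:
        warnings.warn(
            "degree-preserving rewiring accepted no swaps; null realizations "
            "equal the source graph", RuntimeWarning)
    return NullEnsemble(realizations=realizations, model=model)


def nodal_swp(g: BinaryGraph, ensemble: NullEnsemble) -> SWPResult:
    """Nodal small-world propensity of ``g`` against a null ensemble.

    The observed per-node clustering and mean shortest path length are
    divided by the ensemble means of the same quantities; the two ratios
    are multiplied (gamma, as defined) and divided (sigma, classical).
    Entries are NaN wherever a null mean is zero or a path is undefined.
    """
    if ensemble.n_realizations == 0:
        raise ValueError("empty null ensemble")
    n = g.n_nodes
    for r in ensemble.realizations:
        if r.n_nodes != n or r.n_edges != g.n_edges:
            raise ValueError("ensemble realization does not match the source graph")
    c_obs = clustering_coefficient(g)
    l_obs = nodal_path_length(g)
    c_null = np.stack([clustering_coefficient(r) for r in ensemble.realizations])
    l_null = np.stack([nodal_path_length(r) for r in ensemble.realizations])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        c_null_mean = np.nanmean(c_null, axis=0)
        l_null_mean = np.nanmean(l_null, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_ratio = np.where(c_null_mean > 0, c_obs / c_null_mean, np.nan)
        l_ratio = np.where(l_null_mean > 0, l_obs / l_null_mean, np.nan)
        gamma = c_ratio * l_ratio
        sigma = c_ratio / l_ratio
    return SWPResult(gamma=gamma, sigma=sigma, c_ratio=c_ratio, l_ratio=l_ratio,
                     c_null_mean=c_null_mean, l_null_mean=l_null_mean)


class NodalSmallWorldPropensity(BaseEstimator, TransformerMixin):
    """Transformer from per-subject sweeps to gamma-AUC feature tables.

    For each subject and sparsity, a null ensemble is generated and the
    nodal gamma (and sigma) computed; each node's curve across sparsity is
    summarized by its trapezoidal AUC.  ``transform`` returns a wide
    DataFrame (subjects x ``swp_gamma|node`` / ``swp_sigma|node`` columns).
    """

    def __init__(self, null_model: str = "degree_preserving",
                 n_realizations: int = 100, seed: int = 0,
                 swaps_per_edge: int = 10,
                 node_names: list[str] | None = None):
        self.null_model = null_model
        self.n_realizations = n_realizations
        self.seed = seed
        self.swaps_per_edge = swaps_per_edge
        self.node_names = node_names

    def fit(self, X, y=None) -> "NodalSmallWorldPropensity":
        if len(X) == 0:
            raise ValueError("no sweeps given")
        n = X[0].graphs[0].n_nodes
        self.node_names_ = (list(self.node_names) if self.node_names is not None
                            else [f"R{i + 1}" for i in range(n)])
        return self

    def transform(self, X) -> "pd.DataFrame":
        import pandas as pd

        from .metrics import MetricCurve, auc_over_sparsity

        rows = {}
        for si, sweep in enumerate(X):
            gammas, sigmas = [], []
            for gi, g in enumerate(sweep.graphs):
                child = np.random.SeedSequence([self.seed, si, gi])
                ens = generate_null(g, self.null_model, self.n_realizations,
                                    seed=child, swaps_per_edge=self.swaps_per_edge)
                res = nodal_swp(g, ens)
                gammas.append(res.gamma)
                sigmas.append(res.sigma)
            gammas = np.stack(gammas)  # (n_sparsity, n_nodes)
            sigmas = np.stack(sigmas)
            feats = {}
            for j, name in enumerate(self.node_names_):
                for label, mat in (("swp_gamma", gammas), ("swp_sigma", sigmas)):
                    try:
                        curve = MetricCurve(label, name, sweep.sparsities, mat[:, j])
                        feats[f"{label}|{name}"] = auc_over_sparsity(curve).auc
                    except ValueError:
                        feats[f"{label}|{name}"] = float("nan")
            rows[si] = feats
        return pd.DataFrame.from_dict(rows, orient="index").sort_index()
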