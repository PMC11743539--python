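"""Proportional-threshold binarization and the sparsity sweep.

Sparsity is the fraction of all possible edges retained: thresholding at
sparsity s keeps exactly k = round(s * N(N-1)/2) strongest node pairs as
edges of an undirected, unweighted graph.  A sweep applies this across a
grid of sparsities (default 10%..50% in 1% steps, i.e. 41 graphs) so no
downstream conclusion hinges on a single threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import ZMatrix


@dataclass
class BinaryGraph:
    """Undirected binary graph at one sparsity level."""

    adjacency: np.ndarray
    sparsity: float = float("nan")

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be 0 (no self-loops)")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass
class SparsitySweep:
    """Ordered family of binary graphs across increasing sparsities."""

    graphs: list[BinaryGraph]
    sparsities: np.ndarray

    def __post_init__(self) -> None:
        self.sparsities = np.asarray(self.sparsities, dtype=float)
        if len(self.graphs) != len(self.sparsities):
            raise ValueError("graphs and sparsities must align")
        if np.any(np.diff(self.sparsities) <= 0):
            raise ValueError("sparsities must be strictly increasing")

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self):
        return iter(self.graphs)


def edge_count_for_sparsity(sparsity: float, n_nodes: int) -> int:
    """Target edge count k = round(s * N(N-1)/2), half rounded away from zero."""
    m_possible = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(sparsity * m_possible + 0.5))


def proportional_threshold(z: ZMatrix | np.ndarray, sparsity: float,
                           mode: str = "signed") -> BinaryGraph:
    """Keep exactly the k strongest node pairs as edges.

    ``signed`` mode ranks pairs by raw weight (strong negative couplings are
    excluded); ``absolute`` ranks by magnitude.  Exact ties at the cutoff are
    resolved deterministically in favor of the lexicographically smaller
    (i, j) pair, so sparsity -> graph is a pure function.
    """
    w = z.z if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)
    n = w.shape[0]
    if not (0.0 < sparsity <= 1.0):
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    k = edge_count_for_sparsity(sparsity, n)
    if k == 0:
        raise ValueError(f"sparsity {sparsity} rounds to an empty graph at N={n}")
    iu, ju = np.triu_indices(n, k=1)
    weights = w[iu, ju]
    if mode == "absolute":
        weights = np.abs(weights)
    # lexsort: primary key last -> descending weight, then ascending (i, j)
    order = np.lexsort((ju, iu, -weights))
    keep = order[:k]
    a = np.zeros((n, n), dtype=np.uint8)
    a[iu[keep], ju[keep]] = 1
    a |= a.T
    return BinaryGraph(adjacency=a, sparsity=sparsity)


def sparsity_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive arithmetic grid {lo, lo+step, ..., hi} (endpoint within 1e-9)."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    if step <= 0:
        raise ValueError("step must be > 0")
    n_steps = int(math.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(n_steps + 1)


def build_sweep(z: ZMatrix | np.ndarray, lo: float = 0.10, hi: float = 0.50,
                step: float = 0.01, mode: str = "signed") -> SparsitySweep:
    """One thresholded graph per sparsity on the inclusive grid [lo, hi]."""
    grid = sparsity_grid(lo, hi, step)
    graphs = [proportional_threshold(z, s, mode=mode) for s in grid]
    return SparsitySweep(graphs=graphs, sparsities=grid)


def group_mean_matrix(z_stack: np.ndarray | Sequence[ZMatrix]) -> np.ndarray:
    """Element-wise mean connectivity matrix across subjects."""
    if not isinstance(z_stack, np.ndarray):
        z_stack = np.stack([zm.z for zm in z_stack])
    return z_stack.mean(axis=0)


class ProportionalThresholdSweep(BaseEstimator, TransformerMixin):
    """Transformer from stacked z-matrices to per-subject sparsity sweeps.

    Parameters mirror the sweep settings of the study configuration.

    Attributes
    ----------
    sparsities_ : ndarray
        The sparsity grid applied (set during fit).
    """

    def __init__(self, lo: float = 0.10, hi: float = 0.50, step: float = 0.01,
                 mode: str = "signed"):
        self.lo = lo
        self.hi = hi
        self.step = step
        self.mode = mode

    def fit(self, X: np.ndarray, y=None) -> "ProportionalThresholdSweep":
        self.sparsities_ = sparsity_grid(self.lo, self.hi, self.step)
        return self

    def transform(self, X: np.ndarray) -> list[SparsitySweep]:
        """X: (n_subjects, n_regions, n_regions) z array -> list of sweeps."""
        return [build_sweep(z, self.lo, self.hi, self.step, self.mode) for z in X]
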