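"""Independent brute-force oracles for graph metrics.

Deliberately naive pure-python implementations (BFS by hand, triangle
triple-enumeration, simple-path enumeration for betweenness, explicit
trapezoid sums) used only to check the package's vectorized versions.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bfs_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths by per-source BFS; inf if unreachable."""
    n = a.shape[0]
    d = np.full((n, n), math.inf)
    for s in range(n):
        d[s, s] = 0
        q = deque([s])
        while q:
            v = q.popleft()
            for w in range(n):
                if a[v, w] and d[s, w] == math.inf:
                    d[s, w] = d[s, v] + 1
                    q.append(w)
    return d


def degree(a: np.ndarray) -> list[int]:
    return [int(sum(a[i])) for i in range(a.shape[0])]


def clustering(a: np.ndarray) -> list[float]:
    """Exhaustive triple enumeration."""
    n = a.shape[0]
    out = []
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        k = len(nb)
        if k < 2:
            out.append(0.0)
            continue
        links = 0
        for x in range(k):
            for y in range(x + 1, k):
                if a[nb[x], nb[y]]:
                    links += 1
        out.append(2.0 * links / (k * (k - 1)))
    return out


def characteristic_path_length(a: np.ndarray) -> float:
    d = bfs_distances(a)
    vals = [d[i, j] for i in range(len(a)) for j in range(len(a))
            if i != j and math.isfinite(d[i, j])]
    if not vals:
        raise ValueError("no reachable pair")
    return sum(vals) / len(vals)


def global_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = bfs_distances(a)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_efficiency(a: np.ndarray) -> list[float]:
    n = a.shape[0]
    out = []
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        if len(nb) < 2:
            out.append(0.0)
            continue
        sub = a[np.ix_(nb, nb)]
        out.append(global_efficiency(sub))
    return out


def nodal_path_length(a: np.ndarray) -> list[float]:
    d = bfs_distances(a)
    n = a.shape[0]
    out = []
    for i in range(n):
        vals = [d[i, j] for j in range(n) if j != i and math.isfinite(d[i, j])]
        out.append(sum(vals) / len(vals) if vals else math.nan)
    return out


def nodal_efficiency(a: np.ndarray) -> list[float]:
    d = bfs_distances(a)
    n = a.shape[0]
    out = []
    for i in range(n):
        total = sum(1.0 / d[i, j] for j in range(n)
                    if j != i and math.isfinite(d[i, j]) and d[i, j] > 0)
        out.append(total / (n - 1))
    return out


def _all_shortest_paths(a: np.ndarray, s: int, t: int) -> list[list[int]]:
    """Every shortest simple path s -> t, by DFS enumeration of simple paths."""
    n = a.shape[0]
    paths: list[list[int]] = []
    best = [math.inf]

    def dfs(v: int, path: list[int]) -> None:
        if len(path) - 1 > best[0]:
            return
        if v == t:
            if len(path) - 1 < best[0]:
                best[0] = len(path) - 1
                paths.clear()
            if len(path) - 1 == best[0]:
                paths.append(list(path))
            return
        for w in range(n):
            if a[v, w] and w not in path:
                path.append(w)
                dfs(w, path)
                path.pop()

    dfs(s, [s])
    return paths


def betweenness(a: np.ndarray) -> list[float]:
    """Fractional shortest-path betweenness by full path enumeration."""
    n = a.shape[0]
    bc = [0.0] * n
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_shortest_paths(a, s, t)
            if not paths:
                continue
            for p in paths:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(paths)
    return bc


def trapezoid_auc(x: np.ndarray, y: np.ndarray) -> float:
    total = 0.0
    for i in range(len(x) - 1):
        total += 0.5 * (y[i] + y[i + 1]) * (x[i + 1] - x[i])
    return total


def all_labeled_graphs(n: int):
    """Yield adjacency matrices of every labeled graph on n nodes."""
    import itertools

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        a = np.zeros((n, n), dtype=np.uint8)
        for (i, j), b in zip(pairs, bits):
            a[i, j] = a[j, i] = b
        yield a
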