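"""Independent brute-force oracles for graph metrics.

Everything here works by exhaustive enumeration of simple paths (feasible for
N <= 8) and shares no code with the package implementation, so agreement is a
genuine cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np


def enumerate_geodesics(a: np.ndarray, s: int, t: int) -> tuple[float, list[list[int]]]:
    """All shortest paths s -> t by exhaustive DFS over simple paths."""
    n = a.shape[0]
    paths: list[list[int]] = []

    def dfs(u: int, visited: set[int], path: list[int]) -> None:
        if u == t:
            paths.append(list(path))
            return
        for v in range(n):
            if a[u, v] and v not in visited:
                visited.add(v)
                path.append(v)
                dfs(v, visited, path)
                path.pop()
                visited.remove(v)

    dfs(s, {s}, [s])
    if not paths:
        return float("inf"), []
    dmin = min(len(p) - 1 for p in paths)
    return float(dmin), [p for p in paths if len(p) - 1 == dmin]


def brute_distances_and_counts(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for i in range(n):
        d[i, i] = 0.0
        sigma[i, i] = 1.0
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            dist, geos = enumerate_geodesics(a, s, t)
            d[s, t] = dist
            sigma[s, t] = len(geos)
    return d, sigma


def brute_global_efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    d, _ = brute_distances_and_counts(a)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_local_efficiency(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        out[i] = brute_global_efficiency(a[np.ix_(nb, nb)])
    return out


def brute_betweenness(a: np.ndarray) -> np.ndarray:
    """Definitional betweenness: unordered pairs, endpoints excluded."""
    n = a.shape[0]
    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            dist, geos = enumerate_geodesics(a, s, t)
            if not geos:
                continue
            for i in range(n):
                if i in (s, t):
                    continue
                through = sum(1 for p in geos if i in p)
                bc[i] += through / len(geos)
    return bc
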