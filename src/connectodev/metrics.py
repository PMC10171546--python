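"""Nodal and global graph metrics on binary undirected connectomes.

Four measures, the regional/global topology battery of the analysis:

* **degree** — number of edges attached to a node.
* **global efficiency** ``E_glob = 1/(N(N-1)) * sum_{i!=j} 1/d_ij`` with
  ``1/inf := 0`` for disconnected pairs; network integration.
* **local efficiency** — for node i, the global efficiency of the subgraph
  induced by i's neighbours with i removed (nodes with fewer than two
  neighbours score 0); network segregation. A ``nodal`` variant, the mean
  inverse distance from i to every other node in the full graph, is also
  available since both readings circulate in the literature.
* **betweenness centrality** ``B_i = sum_{a!=i!=b} sigma_ab(i)/sigma_ab``
  over unordered pairs, endpoints excluded, unnormalized by default.

Shortest-path lengths and geodesic counts come from breadth-first search
(every graph here is unweighted); betweenness uses the Brandes accumulation
in igraph, whose output equals the definitional sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import numpy as np
import pandas as pd

from .thresholding import BinaryGraph


@dataclass
class DistanceMatrix:
    """Pairwise hop distances ``d`` (inf if unreachable) and geodesic counts ``sigma``."""

    d: np.ndarray
    sigma: np.ndarray


@dataclass
class NodeMetricTable:
    """Per-node metrics for one scan plus its scan-level global efficiency."""

    scan_id: str
    nodes: pd.DataFrame  # region_index, region_label, degree, eloc, bc
    eglob: float


def shortest_paths(g: BinaryGraph) -> DistanceMatrix:
    """BFS from every node, computing distances and geodesic counts together."""
    a = g.A
    n = g.n_nodes
    neighbors = [np.flatnonzero(a[i]) for i in range(n)]
    d = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in range(n):
        d[s, s] = 0.0
        sigma[s, s] = 1.0
        frontier = [s]
        dist = 0
        while frontier:
            dist += 1
            nxt: list[int] = []
            for u in frontier:
                for v in neighbors[u]:
                    if np.isinf(d[s, v]):
                        d[s, v] = dist
                        sigma[s, v] = sigma[s, u]
                        nxt.append(v)
                    elif d[s, v] == dist:
                        sigma[s, v] += sigma[s, u]
            frontier = nxt
    return DistanceMatrix(d=d, sigma=sigma)


def degree(g: BinaryGraph) -> np.ndarray:
    return g.A.sum(axis=1).astype(int)


def _dense_bfs_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs hop distances by synchronous multi-source BFS (matrix steps).

    For the small dense graphs in this pipeline a handful of N x N boolean
    products (one per BFS level) beats per-source traversal by a wide margin.
    """
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    reach = np.eye(n, dtype=bool)
    frontier = reach
    ab = a.astype(bool)
    dist = 0
    while True:
        dist += 1
        nxt = (frontier @ ab) & ~reach
        if not nxt.any():
            break
        d[nxt] = dist
        reach |= nxt
        frontier = nxt
    return d


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d == 0, np.inf, d), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs."""
    if g.n_nodes < 2:
        raise ValueError("global efficiency undefined for fewer than 2 nodes")
    return _efficiency_from_distances(_dense_bfs_distances(g.A))


def local_efficiency(g: BinaryGraph, variant: str = "subgraph") -> np.ndarray:
    """Per-node local efficiency.

    ``variant="subgraph"`` (default): efficiency of the neighbour-induced
    subgraph with the node itself removed. ``variant="nodal"``: mean inverse
    distance from the node to all others in the full graph, i.e.
    ``1/(N-1) * sum_{j!=i} 1/d_ij``.
    """
    n = g.n_nodes
    out = np.zeros(n)
    if variant == "nodal":
        d = _dense_bfs_distances(g.A)
        for i in range(n):
            with np.errstate(divide="ignore"):
                inv = 1.0 / d[i]
            inv[i] = 0.0
            inv[~np.isfinite(d[i])] = 0.0
            out[i] = inv.sum() / (n - 1) if n > 1 else 0.0
        return out
    if variant != "subgraph":
        raise ValueError("variant must be 'subgraph' or 'nodal'")
    for i in range(n):
        nb = np.flatnonzero(g.A[i])
        if nb.size < 2:
            continue
        out[i] = _efficiency_from_distances(_dense_bfs_distances(g.A[np.ix_(nb, nb)]))
    return out


def betweenness_centrality(g: BinaryGraph, normalized: bool = False) -> np.ndarray:
    """Brandes betweenness: endpoints excluded, each unordered pair once.

    Unnormalized by default; ``normalized=True`` divides by (N-1)(N-2)/2.
    The downstream trajectory models are invariant to this scale choice.
    """
    if g.n_nodes == 0:
        return np.zeros(0)
    gx = igraph.Graph.Adjacency(g.A.tolist(), mode="undirected")
    bc = np.asarray(gx.betweenness(directed=False), dtype=float)
    if normalized:
        n = g.n_nodes
        denom = (n - 1) * (n - 2) / 2
        bc = bc / denom if denom > 0 else bc * 0.0
    return bc


def node_metric_table(g: BinaryGraph, scan_id: str = "", eloc_variant: str = "subgraph") -> NodeMetricTable:
    """Assemble degree, local efficiency, betweenness and global efficiency."""
    nodes = pd.DataFrame(
        {
            "region_index": g.kept_nodes,
            "region_label": g.region_labels,
            "degree": degree(g),
            "eloc": local_efficiency(g, variant=eloc_variant),
            "bc": betweenness_centrality(g),
        }
    )
    eglob = global_efficiency(g) if g.n_nodes >= 2 else 0.0
    return NodeMetricTable(scan_id=scan_id, nodes=nodes, eglob=eglob)
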