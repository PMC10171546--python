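"""Binarization of weighted connectomes.

Two schemes, one per modality:

* **Functional** — a single correlation threshold tau applied to every scan,
  with tau chosen from a grid (default 0 to 0.5 in steps of 0.05) as the
  smallest value whose group-averaged network is small-world: global
  efficiency above a degree-matched ring lattice and local efficiency above
  degree-preserving random rewirings, with the network cost (edge density)
  inside an admissible band. Only positive correlations form edges; the grid
  itself is restricted to non-negative tau.

* **Structural** — consistency-based thresholding: for every edge present in
  at least one subject, the coefficient of variation (CV) of its weight
  across subjects is computed, and edges at or below the 75th percentile of
  the CV distribution (the *most consistent* quarter-by-quarter split) are
  retained. Nodes left with zero connections are pruned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph
import networkx as nx
import numpy as np
import pandas as pd

from .io import ConnectivityMatrix

logger = logging.getLogger("connectodev")

#: Grid of candidate functional thresholds.
DEFAULT_TAU_GRID = tuple(np.round(np.arange(0.0, 0.5001, 0.05), 10))

#: Primary functional threshold and its sensitivity companions.
PRIMARY_TAU = 0.15
SENSITIVITY_TAUS = (0.1, 0.15, 0.2)

#: Admissible edge-density band for threshold selection.
DEFAULT_COST_BAND = (0.05, 0.5)

#: Consistency-thresholding percentile for structural CV.
DEFAULT_CV_PERCENTILE = 75.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class BinaryGraph:
    """Undirected, unweighted graph after thresholding.

    ``kept_nodes[k]`` is the original region index of graph node k, so
    regional identity survives isolated-node pruning.
    """

    A: np.ndarray
    kept_nodes: np.ndarray
    region_labels: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        if self.A.dtype != np.uint8:
            self.A = (self.A != 0).astype(np.uint8)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(self.A, self.A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.A)):
            raise ValueError("adjacency diagonal must be zero")
        self.kept_nodes = np.asarray(self.kept_nodes, dtype=int)
        if self.kept_nodes.shape[0] != self.A.shape[0]:
            raise ValueError("kept_nodes length must match adjacency size")
        if len(self.region_labels) != self.A.shape[0]:
            raise ValueError("region_labels length must match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.A)
        g.remove_edges_from(nx.selfloop_edges(g))
        return g


@dataclass
class ThresholdProfile:
    """Small-world diagnostics of one thresholded network (or a group average)."""

    tau: float
    cost: float
    eglob_ratio: float
    eloc_ratio: float
    is_small_world: bool


@dataclass
class ConsistencyMask:
    """Edges retained by consistency thresholding, with the edgewise CV map."""

    mask: np.ndarray
    cv: np.ndarray
    percentile_cut: float


# ---------------------------------------------------------------------------
# Binarization and cost
# ---------------------------------------------------------------------------


def binarize(m: ConnectivityMatrix, tau: float) -> BinaryGraph:
    """Edges where the signed weight strictly exceeds ``tau``; no pruning."""
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    a = (m.W > tau).astype(np.uint8)
    np.fill_diagonal(a, 0)
    return BinaryGraph(a, np.arange(m.n_regions), list(m.region_labels))


def network_cost(g: BinaryGraph) -> float:
    """Edge density: edges present over the N(N-1)/2 possible."""
    n = g.n_nodes
    if n < 2:
        raise ValueError("cost undefined for fewer than 2 nodes")
    return g.n_edges / (n * (n - 1) / 2)


# ---------------------------------------------------------------------------
# Reference networks
# ---------------------------------------------------------------------------


def reference_lattice(g: BinaryGraph) -> BinaryGraph:
    """Ring lattice on the same nodes with the same edge count.

    Built with the nearest even per-node degree at or above the required edge
    count, then trimmed from the outermost ring back to the exact count.
    """
    n = g.n_nodes
    if n < 2:
        raise ValueError("lattice reference needs at least 2 nodes")
    m = g.n_edges
    a = np.zeros((n, n), dtype=np.uint8)
    if m > 0:
        half = int(np.ceil(m / n))  # rings needed; per-node degree 2*half
        half = min(half, (n - 1) // 2 + 1)
        edges: list[tuple[int, int]] = []
        for off in range(1, half + 1):
            ring = [(i, (i + off) % n) for i in range(n)]
            # an offset of exactly n/2 duplicates each edge once
            if 2 * off == n:
                ring = ring[: n // 2]
            edges.extend(tuple(sorted(e)) for e in ring)
        edges = list(dict.fromkeys(edges))
        if len(edges) < m:
            raise ValueError("edge count exceeds lattice capacity")
        for i, j in edges[:m]:  # trim from the outermost ring (appended last)
            a[i, j] = a[j, i] = 1
    return BinaryGraph(a, g.kept_nodes.copy(), list(g.region_labels))


def reference_random(g: BinaryGraph, n_real: int, seed: int, swaps_per_edge: int = 10) -> list[BinaryGraph]:
    """Degree-preserving double-edge-swap rewirings of ``g``; seeded, independent.

    Each realization applies ``swaps_per_edge * |E|`` swap attempts (a swap
    that would duplicate an edge is rejected but still counts, so very dense
    graphs — where few legal swaps exist — terminate promptly and stay close
    to the original, which is the correct degree-preserving null there).
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    import random as _pyrandom  # igraph's rewire draws from the stdlib RNG

    m = g.n_edges
    base = igraph.Graph.Adjacency(g.A.tolist(), mode="undirected")
    out: list[BinaryGraph] = []
    rng = np.random.default_rng(seed)
    for _ in range(n_real):
        gr = base.copy()
        if m >= 2:
            state = _pyrandom.getstate()
            _pyrandom.seed(int(rng.integers(2**31 - 1)))
            try:
                gr.rewire(n=swaps_per_edge * m)
            finally:
                _pyrandom.setstate(state)
        a = np.array(gr.get_adjacency().data, dtype=np.uint8)
        out.append(BinaryGraph(a, g.kept_nodes.copy(), list(g.region_labels)))
    return out


def small_world_profile(
    g: BinaryGraph,
    n_real: int = 10,
    seed: int = 0,
    tau: float = float("nan"),
    margin: float = 1.0,
) -> ThresholdProfile:
    """Small-world diagnostics of one graph against its two references.

    ``eglob_ratio`` compares global efficiency with a degree-matched ring
    lattice; ``eloc_ratio`` is the mean over rewired realizations of the
    graph-mean local efficiency ratio. Small-world means both exceed
    ``margin`` (default 1).
    """
    from .metrics import global_efficiency, local_efficiency

    if g.n_edges < 1:
        raise ValueError("small-world profile undefined for an edgeless graph")
    eglob = global_efficiency(g)
    eglob_lat = global_efficiency(reference_lattice(g))
    eglob_ratio = eglob / eglob_lat if eglob_lat > 0 else np.inf
    eloc = float(local_efficiency(g).mean())
    ratios = []
    for gr in reference_random(g, n_real, seed):
        er = float(local_efficiency(gr).mean())
        ratios.append(eloc / er if er > 0 else np.inf)
    eloc_ratio = float(np.mean(ratios))
    return ThresholdProfile(
        tau=tau,
        cost=network_cost(g),
        eglob_ratio=float(eglob_ratio),
        eloc_ratio=eloc_ratio,
        is_small_world=bool(eglob_ratio > margin and eloc_ratio > margin),
    )


def select_functional_threshold(
    matrices: list[ConnectivityMatrix],
    tau_grid: tuple[float, ...] = DEFAULT_TAU_GRID,
    n_real: int = 10,
    seed: int = 0,
    cost_band: tuple[float, float] = DEFAULT_COST_BAND,
    margin: float = 1.0,
) -> tuple[float, pd.DataFrame]:
    """Choose the functional threshold from a grid by small-worldness.

    Per tau, profiles are computed per scan and averaged; the chosen tau is
    the smallest whose averaged profile is small-world with mean cost inside
    ``cost_band`` (the densest admissible network). The full profile table is
    returned for reporting and sensitivity analysis.
    """
    if not matrices:
        raise ValueError("need at least one connectivity matrix")
    if not len(tau_grid):
        raise ValueError("tau grid is empty")
    rows = []
    for k, tau in enumerate(sorted(tau_grid)):
        costs, eg, el = [], [], []
        for i, m in enumerate(matrices):
            g = binarize(m, tau)
            costs.append(network_cost(g))
            if g.n_edges == 0:
                continue
            prof = small_world_profile(g, n_real=n_real, seed=seed + 1000 * k + i, tau=tau)
            eg.append(prof.eglob_ratio)
            el.append(prof.eloc_ratio)
        mean_cost = float(np.mean(costs))
        mean_eg = float(np.mean(eg)) if eg else np.nan
        mean_el = float(np.mean(el)) if el else np.nan
        sw = bool(
            np.isfinite(mean_eg) and np.isfinite(mean_el)
            and mean_eg > margin and mean_el > margin
        )
        rows.append(
            {
                "tau": float(tau),
                "cost": mean_cost,
                "eglob_ratio": mean_eg,
                "eloc_ratio": mean_el,
                "is_small_world": sw,
                "in_cost_band": bool(cost_band[0] <= mean_cost <= cost_band[1]),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table.is_small_world & table.in_cost_band]
    if ok.empty:
        raise ValueError(
            "no threshold in the grid yields a small-world network inside the "
            f"cost band {cost_band}; widen the grid or the band"
        )
    return float(ok.tau.iloc[0]), table


# ---------------------------------------------------------------------------
# Structural consistency thresholding
# ---------------------------------------------------------------------------


def consistency_threshold(
    stack: list[ConnectivityMatrix],
    percentile: float = DEFAULT_CV_PERCENTILE,
    keep: str = "low_cv",
) -> ConsistencyMask:
    """Across-subject consistency mask for structural connectomes.

    Candidate edges are those present (nonzero) in at least one subject. For
    each, the coefficient of variation sd/mean of the weight across *all*
    subjects is computed; edges with CV at or below the ``percentile``-th
    percentile of the candidate CV distribution are retained (low CV = the
    edge is reconstructed consistently). ``keep="high_cv"`` selects the
    complement, for comparison with the alternative reading of the rule.
    """
    if len(stack) < 2:
        raise ValueError("consistency thresholding needs at least 2 subjects")
    labels = stack[0].region_labels
    n = stack[0].n_regions
    for m in stack[1:]:
        if m.n_regions != n or m.region_labels != labels:
            raise ValueError("all matrices must share shape and region labels")
    w = np.stack([m.W for m in stack])  # S x N x N
    present = (w != 0).any(axis=0)
    np.fill_diagonal(present, False)
    mean = w.mean(axis=0)
    sd = w.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    candidate = present & (mean > 0)
    iu = np.triu_indices(n, k=1)
    cand_cv = cv[iu][candidate[iu]]
    if cand_cv.size == 0:
        raise ValueError("no candidate edges (all-zero stack?)")
    cut = float(np.percentile(cand_cv, percentile))
    # ties at the cut are retained; the epsilon absorbs float noise (e.g. the
    # all-identical stack, where sd of equal values lands at ~1e-16, not 0)
    tol = cut * (1 + 1e-9) + 1e-12
    if keep == "low_cv":
        mask = candidate & (cv <= tol)
    elif keep == "high_cv":
        mask = candidate & (cv > tol)
    else:
        raise ValueError("keep must be 'low_cv' or 'high_cv'")
    mask = mask | mask.T
    return ConsistencyMask(mask=mask, cv=cv, percentile_cut=cut)


def apply_mask_and_prune(m: ConnectivityMatrix, mask: ConsistencyMask) -> BinaryGraph:
    """Binarize through a consistency mask and drop zero-degree nodes."""
    if mask.mask.shape != m.W.shape:
        raise ValueError("mask and matrix shapes differ")
    a = ((m.W > 0) & mask.mask).astype(np.uint8)
    np.fill_diagonal(a, 0)
    deg = a.sum(axis=1)
    keep = np.flatnonzero(deg > 0)
    if keep.size == 0:
        return BinaryGraph(np.zeros((0, 0), dtype=np.uint8), keep, [])
    a = a[np.ix_(keep, keep)]
    labels = [m.region_labels[i] for i in keep]
    return BinaryGraph(a, keep, labels)
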