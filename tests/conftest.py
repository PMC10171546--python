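from __future__ import annotations

import numpy as np
import pytest

from connectodev.simulate import CohortSpec, default_template, generate_phenotypes
from connectodev.thresholding import BinaryGraph


def graph_from_edges(n: int, edges: list[tuple[int, int]]) -> BinaryGraph:
    a = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryGraph(a, np.arange(n), [f"n{i}" for i in range(n)])


def random_graph(n: int, p: float, rng: np.random.Generator) -> BinaryGraph:
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    a = (a | a.T).astype(np.uint8)
    return BinaryGraph(a, np.arange(n), [f"n{i}" for i in range(n)])


def ring_lattice(n: int, k: int) -> BinaryGraph:
    """Ring lattice: each node tied to its k nearest neighbours (k even)."""
    a = np.zeros((n, n), dtype=np.uint8)
    for off in range(1, k // 2 + 1):
        for i in range(n):
            j = (i + off) % n
            a[i, j] = a[j, i] = 1
    return BinaryGraph(a, np.arange(n), [f"n{i}" for i in range(n)])


@pytest.fixture
def path3() -> BinaryGraph:
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def cycle4() -> BinaryGraph:
    return graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


@pytest.fixture
def star5() -> BinaryGraph:
    return graph_from_edges(5, [(0, i) for i in range(1, 5)])


@pytest.fixture(scope="session")
def small_template():
    return default_template(n_regions=30, n_modules=5, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(n_per_group=8, seed=21)
    return spec, generate_phenotypes(spec)
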