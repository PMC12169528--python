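"""Shared fixtures and independent oracles for the test suite.

The oracle implementations here are deliberately naive (dense linear solves,
exhaustive path enumeration, literal recurrences in exact arithmetic) so they
stay independent of the package's computation paths.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction

import numpy as np
import pytest

from infodemic import InteractionNetwork, SyntheticSpec, generate_network


# -- small fixed graphs ----------------------------------------------------


@pytest.fixture
def path_abc():
    """Directed path a -> b -> c."""
    return InteractionNetwork.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def triangle_cycle():
    """Directed 3-cycle a -> b -> c -> a."""
    return InteractionNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def star_out():
    """Centre s with out-edges to x, y, z."""
    return InteractionNetwork.from_edges([("s", "x"), ("s", "y"), ("s", "z")])


@pytest.fixture(scope="session")
def planted_default():
    """One default-condition synthetic network with its ground truth."""
    return generate_network(SyntheticSpec(seed=20260927))


# -- random graph helper ---------------------------------------------------


def random_digraph(rng: np.random.Generator, n: int, p: float = 0.3,
                   weighted: bool = False) -> InteractionNetwork:
    nodes = [f"n{i:03d}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                w = float(rng.integers(1, 5)) if weighted else 1.0
                edges.append((nodes[i], nodes[j], w))
    return InteractionNetwork.from_edges(edges, nodes=nodes)


# -- oracle: exhaustive betweenness ----------------------------------------


def brute_force_betweenness(net: InteractionNetwork) -> dict:
    """Enumerate every shortest path of every ordered pair (tiny n only)."""
    nodes = net.nodes
    adj = {v: sorted(net.out_neighbours(v)) for v in nodes}
    scores = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        dist = {s: 0}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        for t in nodes:
            if t == s or t not in dist:
                continue
            paths: list[tuple] = []

            def extend(prefix):
                u = prefix[-1]
                if u == t:
                    paths.append(tuple(prefix))
                    return
                for v in adj[u]:
                    if v in dist and dist[v] == dist[u] + 1 and dist[v] <= dist[t]:
                        extend(prefix + [v])

            extend([s])
            sigma = len(paths)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                if through:
                    scores[v] += through / sigma
    return scores


# -- oracle: propagation fixed point by direct linear solve ----------------


def pc_linear_solve(net: InteractionNetwork, damping: float = 0.85,
                    dangling_mode: str = "literal") -> dict:
    nodes = net.nodes
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    out_deg = {v: net.degree_of(v, "out") for v in nodes}
    for u, v, _ in net.edges():
        M[idx[v], idx[u]] = 1.0 / out_deg[u]
    if dangling_mode == "redistribute":
        for u in nodes:
            if out_deg[u] == 0:
                M[:, idx[u]] = 1.0 / n
    x = np.linalg.solve(np.eye(n) - damping * M, np.full(n, (1 - damping) / n))
    return {v: float(x[idx[v]]) for v in nodes}


# -- oracle: DIC via repeated exact matrix application ---------------------


def dic_matrix_power(net: InteractionNetwork, steps: int) -> np.ndarray:
    """(I + B^T)^steps 1 computed with Python integers (exact)."""
    nodes = net.nodes
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    B = [[0] * n for _ in range(n)]
    for u, v, _ in net.edges():
        B[idx[v]][idx[u]] = 1  # row v accumulates from in-neighbour u
    vec = [1] * n
    for _ in range(steps):
        vec = [vec[i] + sum(B[i][j] * vec[j] for j in range(n)) for i in range(n)]
    return np.array(vec, dtype=object)


# -- oracle: MVC literal recurrence in exact rational arithmetic -----------


def mvc_recurrence_exact(degrees: list[int], vul0: list[Fraction], steps: int) -> list[Fraction]:
    vals = list(vul0)
    for _ in range(steps):
        vals = [d * v for d, v in zip(degrees, vals)]
    return vals
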