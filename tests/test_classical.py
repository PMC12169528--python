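"""Degree, closeness (standard/harmonic), betweenness and eigenvector baselines."""

import itertools

import numpy as np
import pytest

from infodemic import (
    InteractionNetwork,
    NonConvergenceError,
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
)
from conftest import brute_force_betweenness, random_digraph


def complete_digraph(n):
    nodes = [f"v{i}" for i in range(n)]
    return InteractionNetwork.from_edges(
        [(u, v) for u, v in itertools.permutations(nodes, 2)]
    )


class TestDegree:
    def test_star_counts_by_mode(self, star_out):
        out = degree_centrality(star_out, mode="out").scores
        assert out == {"s": 3.0, "x": 0.0, "y": 0.0, "z": 0.0}
        inn = degree_centrality(star_out, mode="in").scores
        assert inn == {"s": 0.0, "x": 1.0, "y": 1.0, "z": 1.0}

    def test_complete_digraph_is_symmetric(self):
        scores = degree_centrality(complete_digraph(4), mode="in").scores
        assert set(scores.values()) == {3.0}

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            degree_centrality(InteractionNetwork())

    def test_counts_match_merged_edge_rows(self):
        rng = np.random.default_rng(5)
        net = random_digraph(rng, 15, p=0.25)
        for mode in ("in", "out", "total"):
            sv = degree_centrality(net, mode=mode)
            for v in net.nodes:
                expected = sum(
                    (mode in ("out", "total") and u == v)
                    + (mode in ("in", "total") and t == v)
                    for u, t, _ in net.edges()
                )
                assert sv.scores[v] == expected


class TestCloseness:
    def test_standard_on_undirected_path(self):
        # a-b-c as reciprocal directed edges
        net = InteractionNetwork.from_edges(
            [("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")]
        )
        sv = closeness_centrality(net, formulation="standard")
        assert sv.scores["b"] == pytest.approx(0.5)
        assert sv.scores["a"] == pytest.approx(1 / 3)

    def test_harmonic_unreachable_terms_contribute_zero(self, star_out):
        sv = closeness_centrality(star_out, formulation="harmonic", direction="outgoing")
        assert sv.scores["s"] == 3.0
        assert sv.scores["x"] == 0.0

    def test_auto_falls_back_to_harmonic_on_fragmented_graph(self):
        net = InteractionNetwork.from_edges(
            [("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")]
        )
        sv = closeness_centrality(net, formulation="auto")
        assert sv.params["formulation_used"] == "harmonic"
        assert sv.scores["a"] == 1.0

    def test_standard_errors_when_pairs_unreachable(self, star_out):
        with pytest.raises(ValueError, match="harmonic"):
            closeness_centrality(star_out, formulation="standard")

    def test_harmonic_monotone_under_edge_addition(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            net = random_digraph(rng, 8, p=0.2)
            before = closeness_centrality(net, formulation="harmonic").scores
            candidates = [
                (u, v) for u in net.nodes for v in net.nodes
                if u != v and v not in net.out_neighbours(u)
            ]
            if not candidates:
                continue
            u, v = candidates[int(rng.integers(len(candidates)))]
            bigger = InteractionNetwork.from_edges(
                net.edges() + [(u, v, 1.0)], nodes=net.nodes
            )
            after = closeness_centrality(bigger, formulation="harmonic").scores
            assert after[u] >= before[u] - 1e-12


class TestBetweenness:
    def test_path_interior_node(self, path_abc):
        sv = betweenness_centrality(path_abc)
        assert sv.scores == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_three_cycle_symmetry(self, triangle_cycle):
        sv = betweenness_centrality(triangle_cycle)
        assert set(sv.scores.values()) == {1.0}

    def test_matches_exhaustive_enumeration_on_random_digraphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(3, 9))
            net = random_digraph(rng, n, p=0.35)
            got = betweenness_centrality(net).scores
            want = brute_force_betweenness(net)
            for v in net.nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-9)

    def test_weighted_uses_inverse_weight_distances(self):
        # heavy a->b->c route (dist 0.25+0.25) beats the direct a->c (dist 1)
        net = InteractionNetwork.from_edges(
            [("a", "b", 4.0), ("b", "c", 4.0), ("a", "c", 1.0)]
        )
        assert betweenness_centrality(net, weighted=True).scores["b"] == 1.0
        assert betweenness_centrality(net, weighted=False).scores["b"] == 0.0


class TestEigenvector:
    def test_complete_digraph_uniform(self):
        sv, summary = eigenvector_centrality(complete_digraph(3))
        assert all(s == pytest.approx(1 / np.sqrt(3)) for s in sv.scores.values())
        assert summary.dominant_eigenvalue == pytest.approx(2.0, abs=1e-4)

    def test_reciprocal_pair_dominates_isolated_node(self):
        net = InteractionNetwork.from_edges([("a", "b"), ("b", "a")], nodes=["c"])
        sv, _ = eigenvector_centrality(net, epsilon_teleport=1e-6)
        assert sv.scores["a"] == pytest.approx(sv.scores["b"])
        assert sv.scores["a"] > sv.scores["c"] > 0.0

    def test_matches_dense_eigensolver_on_random_digraphs(self):
        # the teleport term is sized so the spectral gap keeps power
        # iteration practical even when the raw adjacency has near-tied
        # complex eigenvalue pairs (e.g. long directed cycles)
        rng = np.random.default_rng(99)
        eps = 0.1
        for _ in range(15):
            n = int(rng.integers(3, 21))
            net = random_digraph(rng, n, p=0.3)
            if net.m == 0:
                continue
            sv, summary = eigenvector_centrality(
                net, tol=1e-12, max_iter=200000, epsilon_teleport=eps
            )
            nodes = net.nodes
            idx = {v: i for i, v in enumerate(nodes)}
            M = np.full((n, n), eps / n)
            for u, v, _ in net.edges():
                M[idx[v], idx[u]] += 1.0
            w, V = np.linalg.eig(M)
            lead = np.argmax(w.real)
            vec = np.abs(V[:, lead].real)
            vec /= np.linalg.norm(vec)
            for v in nodes:
                assert sv.scores[v] == pytest.approx(vec[idx[v]], abs=1e-6)
            assert summary.dominant_eigenvalue == pytest.approx(w[lead].real, abs=1e-6)

    def test_scores_positive_and_relabelling_invariant(self):
        rng = np.random.default_rng(17)
        net = random_digraph(rng, 10, p=0.3)
        sv, _ = eigenvector_centrality(net)
        assert all(s > 0 for s in sv.scores.values())
        relabel = {v: f"zz_{v}" for v in net.nodes}
        net2 = InteractionNetwork.from_edges(
            [(relabel[u], relabel[v], w) for u, v, w in net.edges()],
            nodes=[relabel[v] for v in net.nodes],
        )
        sv2, _ = eigenvector_centrality(net2)
        for v in net.nodes:
            assert sv2.scores[relabel[v]] == pytest.approx(sv.scores[v], abs=1e-8)

    def test_nonconvergence_raises_with_residual(self):
        # asymmetric graph: the uniform start is not already the eigenvector
        net = InteractionNetwork.from_edges([("a", "b"), ("a", "c"), ("b", "c")])
        with pytest.raises(NonConvergenceError) as err:
            eigenvector_centrality(net, tol=1e-300, max_iter=2)
        assert err.value.residual > 0
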