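"""Propagation, vulnerability and dynamic-influence centralities."""

from fractions import Fraction

import numpy as np
import pytest

from infodemic import (
    InteractionNetwork,
    PCParams,
    SyntheticSpec,
    dynamic_influence_centrality,
    generate_network,
    initialise_vulnerability,
    misinformation_vulnerability_centrality,
    persistence_profile,
    propagation_centrality,
)
from infodemic.network import NodeAttributeTable
from conftest import dic_matrix_power, mvc_recurrence_exact, pc_linear_solve, random_digraph


class TestPropagationCentrality:
    def test_edgeless_graph_gets_pure_teleport_score(self):
        net = InteractionNetwork.from_edges([], nodes=list("abcd"))
        sv, _ = propagation_centrality(net)
        assert all(s == (1 - 0.85) / 4 for s in sv.scores.values())

    def test_reciprocal_pair_fixed_point(self):
        net = InteractionNetwork.from_edges([("a", "b"), ("b", "a")])
        sv, _ = propagation_centrality(net)
        assert sv.scores["a"] == pytest.approx(0.5, abs=1e-9)
        assert sv.scores["b"] == pytest.approx(0.5, abs=1e-9)

    def test_three_node_fixed_point_matches_direct_solve(self):
        net = InteractionNetwork.from_edges([("a", "b"), ("a", "c"), ("b", "c")])
        sv, summary = propagation_centrality(net)
        assert sv.scores["a"] == pytest.approx(0.05, abs=1e-9)
        assert sv.scores["b"] == pytest.approx(0.07125, abs=1e-9)
        assert sv.scores["c"] == pytest.approx(0.1318125, abs=1e-9)
        assert summary.converged

    @pytest.mark.parametrize("dangling_mode", ["literal", "redistribute"])
    def test_matches_linear_solve_on_random_digraphs(self, dangling_mode):
        rng = np.random.default_rng(314)
        for _ in range(30):
            n = int(rng.integers(2, 51))
            net = random_digraph(rng, n, p=0.15)
            sv, _ = propagation_centrality(
                net, dangling_mode=dangling_mode, tol=1e-13, max_iter=3000
            )
            oracle = pc_linear_solve(net, dangling_mode=dangling_mode)
            for v in net.nodes:
                assert sv.scores[v] == pytest.approx(oracle[v], abs=1e-8)

    def test_scores_bounded_and_sum_to_one_without_dangling_nodes(self, triangle_cycle):
        sv, _ = propagation_centrality(triangle_cycle)
        assert sum(sv.scores.values()) == pytest.approx(1.0, abs=1e-8)
        assert all(0 <= s <= 1 for s in sv.scores.values())

    def test_redistribute_mode_conserves_mass_with_dangling_nodes(self, path_abc):
        sv, summary = propagation_centrality(path_abc, dangling_mode="redistribute")
        assert sum(sv.scores.values()) == pytest.approx(1.0, abs=1e-8)
        assert summary.dominant_eigenvalue == pytest.approx(1.0, abs=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        net = random_digraph(rng, 12, p=0.3)
        sv, _ = propagation_centrality(net)
        relabel = {v: f"x{v}" for v in net.nodes}
        net2 = InteractionNetwork.from_edges(
            [(relabel[u], relabel[v], w) for u, v, w in net.edges()],
            nodes=list(relabel.values()),
        )
        sv2, _ = propagation_centrality(net2)
        for v in net.nodes:
            assert sv2.scores[relabel[v]] == pytest.approx(sv.scores[v], abs=1e-12)

    def test_max_iter_reached_is_flagged_not_fatal(self):
        net = InteractionNetwork.from_edges([("a", "b"), ("a", "c"), ("b", "c")])
        with pytest.warns(RuntimeWarning, match="max_iter"):
            _, summary = propagation_centrality(net, tol=1e-300, max_iter=2)
        assert not summary.converged

    def test_invalid_damping_rejected(self, triangle_cycle):
        with pytest.raises(ValueError):
            PCParams(damping=1.0)


class TestVulnerabilityInitialisation:
    def test_seeded_draws_are_reproducible(self, path_abc):
        a = initialise_vulnerability(path_abc, seed=42)
        b = initialise_vulnerability(path_abc, seed=42)
        assert np.array_equal(a.values, b.values)
        c = initialise_vulnerability(path_abc, seed=43)
        assert not np.array_equal(a.values, c.values)

    def test_attribute_vul0_used_verbatim(self, path_abc):
        attrs = NodeAttributeTable.from_mapping(
            {"vul0": {"a": 0.5, "b": 0.5, "c": 0.5}}
        )
        state = initialise_vulnerability(path_abc, attrs=attrs)
        assert state.source == "attributes"
        assert set(state.vul0().values()) == {0.5}

    def test_single_feature_column_is_minmax_rescaled(self, path_abc):
        attrs = NodeAttributeTable.from_mapping(
            {"retweet_count": {"a": 0, "b": 10, "c": 20}}
        )
        state = initialise_vulnerability(path_abc, attrs=attrs)
        assert state.vul0() == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_partial_attribute_coverage_rejected(self, path_abc):
        attrs = NodeAttributeTable.from_mapping({"vul0": {"a": 0.5, "b": 0.5}})
        with pytest.raises(ValueError, match="cover"):
            initialise_vulnerability(path_abc, attrs=attrs)

    def test_no_source_at_all_rejected(self, path_abc):
        with pytest.raises(ValueError, match="seed"):
            initialise_vulnerability(path_abc)


class TestVulnerabilityCentrality:
    def test_raw_score_is_degree_power_times_initial(self):
        # b has in-degree 2; with vul0 = 0.5 and 3 steps the raw value is 4
        net = InteractionNetwork.from_edges([("a", "b"), ("c", "b")])
        attrs = NodeAttributeTable.from_mapping(
            {"vul0": {"a": 0.25, "b": 0.5, "c": 1.0}}
        )
        init = initialise_vulnerability(net, attrs=attrs)
        _, traj = misinformation_vulnerability_centrality(net, init, steps=3)
        assert traj.values[-1].tolist() == [0.0, 4.0, 0.0]  # in-deg 0 decays to 0

    def test_minmax_normalisation_of_raw_vector(self):
        # in-degrees 0, 1, 2 with vul0 1 -> raw (0, 1, 4) after 2 steps... use
        # a direct construction giving raw (0, 4, 8)
        net = InteractionNetwork.from_edges(
            [("a", "b"), ("b", "c"), ("a", "c")], nodes=["a"]
        )
        attrs = NodeAttributeTable.from_mapping({"vul0": {"a": 0.5, "b": 1.0, "c": 0.5}})
        init = initialise_vulnerability(net, attrs=attrs)
        sv, traj = misinformation_vulnerability_centrality(net, init, steps=2)
        assert traj.values[-1].tolist() == [0.0, 1.0, 2.0]
        assert sv.scores == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_degenerate_minmax_maps_to_midpoint(self):
        net = InteractionNetwork.from_edges([("a", "b"), ("b", "a")])
        attrs = NodeAttributeTable.from_mapping({"vul0": {"a": 0.3, "b": 0.3}})
        init = initialise_vulnerability(net, attrs=attrs)
        sv, _ = misinformation_vulnerability_centrality(net, init)
        assert sv.scores == {"a": 0.5, "b": 0.5}

    def test_recurrence_matches_exact_closed_form(self):
        """Literal recurrence == degree^steps * vul0 in exact arithmetic.

        Instances use dyadic vul0 and small degrees so every float product is
        exact and the comparison is equality, not approximation.
        """
        rng = np.random.default_rng(271828)
        for _ in range(100):
            n = int(rng.integers(2, 11))
            net = random_digraph(rng, n, p=0.3)
            vul0 = {v: float(rng.integers(0, 1025)) / 1024.0 for v in net.nodes}
            steps = int(rng.integers(1, 6))
            attrs = NodeAttributeTable.from_mapping({"vul0": vul0})
            init = initialise_vulnerability(net, attrs=attrs)
            sv, traj = misinformation_vulnerability_centrality(net, init, steps=steps)
            degrees = [net.degree_of(v, "in") for v in net.nodes]
            exact = mvc_recurrence_exact(
                degrees, [Fraction(vul0[v]) for v in net.nodes], steps
            )
            for i, v in enumerate(net.nodes):
                assert traj.values[-1, i] == float(exact[i])
            assert all(0.0 <= s <= 1.0 for s in sv.scores.values())

    def test_ranking_by_degree_when_vul0_constant_is_steps_invariant(self):
        rng = np.random.default_rng(5)
        net = random_digraph(rng, 12, p=0.3)
        attrs = NodeAttributeTable.from_mapping({"vul0": {v: 0.7 for v in net.nodes}})
        init = initialise_vulnerability(net, attrs=attrs)
        orders = []
        for steps in (1, 3, 5):
            sv, _ = misinformation_vulnerability_centrality(net, init, steps=steps)
            orders.append(sv.ranking())
        assert orders[0] == orders[1] == orders[2]

    def test_large_degree_powers_handled_in_log_space(self):
        hub_edges = [(f"s{i:03d}", "hub") for i in range(400)]
        net = InteractionNetwork.from_edges(hub_edges + [("hub", "s000"), ("s001", "s000")])
        init = initialise_vulnerability(net, seed=1)
        sv, _ = misinformation_vulnerability_centrality(net, init, steps=10)
        assert all(np.isfinite(s) and 0 <= s <= 1 for s in sv.scores.values())
        assert max(sv.scores, key=sv.scores.get) == "hub"

    def test_step_bounds_enforced(self, path_abc):
        init = initialise_vulnerability(path_abc, seed=0)
        with pytest.raises(ValueError):
            misinformation_vulnerability_centrality(path_abc, init, steps=0)
        with pytest.raises(ValueError, match="ceiling"):
            misinformation_vulnerability_centrality(path_abc, init, steps=11)


class TestDynamicInfluence:
    def test_path_fixture_hand_iteration(self, path_abc):
        sv, traj = dynamic_influence_centrality(path_abc, steps=2)
        assert traj.values.tolist() == [[1, 1, 1], [1, 2, 2], [1, 3, 4]]
        assert sv.scores == {"a": 0.25, "b": 0.75, "c": 1.0}

    def test_reciprocal_pair_doubles_each_step(self):
        net = InteractionNetwork.from_edges([("a", "b"), ("b", "a")])
        _, traj = dynamic_influence_centrality(net, steps=6)
        assert traj.values[:, 0].tolist() == [2**t for t in range(7)]

    def test_isolated_node_stays_at_one(self):
        net = InteractionNetwork.from_edges([], nodes=["x", "y"])
        sv, traj = dynamic_influence_centrality(net, steps=4)
        assert set(traj.values.ravel().tolist()) == {1}
        assert sv.scores == {"x": 1.0, "y": 1.0}  # everyone is the max

    def test_matches_matrix_power_oracle(self):
        rng = np.random.default_rng(1618)
        for _ in range(30):
            n = int(rng.integers(2, 31))
            net = random_digraph(rng, n, p=0.2)
            steps = int(rng.integers(1, 11))
            _, traj = dynamic_influence_centrality(net, steps=steps)
            oracle = dic_matrix_power(net, steps)
            assert [int(x) for x in traj.values[-1]] == [int(x) for x in oracle]

    def test_trajectory_is_entrywise_non_decreasing(self):
        rng = np.random.default_rng(44)
        net = random_digraph(rng, 20, p=0.25)
        _, traj = dynamic_influence_centrality(net, steps=8)
        assert (np.diff(traj.values.astype(float), axis=0) >= 0).all()

    def test_overflow_guard_recommends_fewer_steps(self):
        import itertools
        nodes = [f"v{i}" for i in range(12)]
        net = InteractionNetwork.from_edges(
            [(u, v) for u, v in itertools.permutations(nodes, 2)]
        )
        with pytest.raises(ValueError, match="fewer steps"):
            dynamic_influence_centrality(net, steps=16)


class TestPersistenceProfile:
    def test_always_top_node_has_maximal_count(self, path_abc):
        _, traj = dynamic_influence_centrality(path_abc, steps=4)
        profile = persistence_profile(traj, k=1)
        assert profile[0] == "c"

    def test_edgeless_graph_ties_resolve_by_node_id(self):
        net = InteractionNetwork.from_edges([], nodes=["b", "a", "c"])
        _, traj = dynamic_influence_centrality(net, steps=2)
        assert persistence_profile(traj, k=2) == ["a", "b", "c"]

    def test_k_larger_than_n_rejected(self, path_abc):
        _, traj = dynamic_influence_centrality(path_abc, steps=2)
        with pytest.raises(ValueError):
            persistence_profile(traj, k=4)

    def test_planted_persistent_spreader_ranks_first(self):
        spec = SyntheticSpec(
            n=60, attachment_out=2, planted_hubs=0, planted_vulnerable=0,
            planted_persistent=1, seed=5,
        )
        net, _, manifest = generate_network(spec)
        _, traj = dynamic_influence_centrality(net, steps=10)
        profile = persistence_profile(traj, k=5)
        assert profile[0] == manifest["planted_persistent"][0]
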