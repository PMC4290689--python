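"""Planted-path generator, perturbation operations and recovery scoring."""

import numpy as np
import pytest

import tempoflow as tf


class TestGenerator:
    def test_deterministic_for_fixed_seed(self):
        spec = tf.SyntheticSpec(n_genes=50, n_paths=3, path_len=2,
                                background_edges=60, seed=7)
        a = tf.generate_planted_network(spec)
        b = tf.generate_planted_network(spec)
        assert {(i.source, i.target, i.weight) for i in a[0]} == \
               {(i.source, i.target, i.weight) for i in b[0]}
        assert a[1] == b[1]
        assert a[2].planted_edges == b[2].planted_edges

    def test_zero_paths_gives_pure_background(self):
        spec = tf.SyntheticSpec(n_genes=30, n_paths=0, background_edges=40,
                                seed=3)
        net, part, truth = tf.generate_planted_network(spec)
        assert not truth.planted_edges
        assert not part.all_genes
        assert len(net) == 80  # bidirectional background: 2 arcs per edge

    def test_planted_structure(self, small_spec, small_instance):
        net, part, truth = small_instance
        assert truth.planted_transit_genes <= set(part.intermediate)
        assert truth.planted_interior_unscored.isdisjoint(part.all_genes)
        assert len(part.early) == small_spec.n_paths
        assert len(part.late) == small_spec.n_paths
        # planted edges exist in the network with above-background weights
        for u, v in truth.planted_edges:
            inter = net.get(u, v)
            assert inter is not None
            assert inter.weight >= small_spec.planted_weight_dist[0]

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            tf.SyntheticSpec(n_genes=10, n_paths=5, path_len=2)
        with pytest.raises(ValueError):
            tf.SyntheticSpec(planted_weight_dist=(0.2, 0.4),
                             background_weight_dist=(0.3, 0.5))

    def test_config_round_trip(self, small_spec):
        assert tf.SyntheticSpec.from_config(small_spec.to_config()) == small_spec


class TestPerturbations:
    def test_add_zero_is_identity(self, small_instance):
        net, _, _ = small_instance
        out = tf.perturb_add_edges(net, 0, seed=1)
        assert out.ordered_pairs == net.ordered_pairs

    def test_add_reproducible_and_disjoint(self, small_instance):
        net, _, _ = small_instance
        a = tf.perturb_add_edges(net, 10, seed=5)
        b = tf.perturb_add_edges(net, 10, seed=5)
        assert a.ordered_pairs == b.ordered_pairs
        new = a.ordered_pairs - net.ordered_pairs
        assert len(new) == 20  # bidirectional additions: 2 ordered arcs each
        assert not (new & net.ordered_pairs)

    def test_add_then_remove_added_restores_network(self, small_instance):
        net, _, _ = small_instance
        added = tf.perturb_add_edges(net, 15, seed=9)
        protect = net.ordered_pairs
        restored = tf.perturb_remove_edges(added, 15, seed=0, exclude=protect)
        assert restored.ordered_pairs == net.ordered_pairs

    def test_remove_counts(self, small_instance):
        net, _, _ = small_instance
        n_records = len(net.undirected_interactions())
        out = tf.perturb_remove_edges(net, 12, seed=2)
        assert len(out.undirected_interactions()) == n_records - 12

    def test_remove_respects_exclusions(self, small_instance):
        net, _, truth = small_instance
        out = tf.perturb_remove_edges(net, 30, seed=4,
                                      exclude=truth.planted_edges)
        assert truth.planted_edges <= out.ordered_pairs

    def test_remove_too_many_rejected(self, small_instance):
        net, _, _ = small_instance
        with pytest.raises(ValueError):
            tf.perturb_remove_edges(net, 10**6, seed=0)

    def test_distinct_seeds_distinct_removals(self, small_instance):
        net, _, _ = small_instance
        sets = [tf.perturb_remove_edges(net, 20, seed=s).ordered_pairs
                for s in range(5)]
        assert len({frozenset(s) for s in sets}) == 5


class TestEvaluateRecovery:
    def _rn_from_edges(self, pairs, truth):
        genes = {g for p in pairs for g in p}
        nodes = [tf.ResponseNode(g, "NOD", 1.0) for g in sorted(genes)]
        edges = [tf.ResponseEdge(u, v, tf.Directionality.UNIDIRECTIONAL, 1.0, 0.9)
                 for u, v in sorted(pairs)]
        return tf.ResponseNetwork(nodes=nodes, edges=edges)

    def test_perfect_recovery_on_planted_network(self, small_instance,
                                                 small_result):
        _, _, truth = small_instance
        m = tf.evaluate_recovery(small_result.response, truth)
        assert 0 <= m.edge_precision <= 1
        assert m.edge_recall == pytest.approx(1.0)
        assert m.transit_recall == pytest.approx(1.0)

    def test_empty_prediction_scores_zero_recall(self, small_instance):
        _, _, truth = small_instance
        m = tf.evaluate_recovery(tf.ResponseNetwork(), truth)
        assert m.edge_recall == 0.0
        assert m.edge_precision == 0.0

    def test_half_recovered_no_extras(self, small_instance):
        _, _, truth = small_instance
        half = set(sorted(truth.planted_edges)[: len(truth.planted_edges) // 2])
        m = tf.evaluate_recovery(self._rn_from_edges(half, truth), truth)
        assert m.edge_recall == pytest.approx(0.5, abs=0.02)
        assert m.edge_precision == 1.0

    def test_empty_ground_truth_is_error(self):
        with pytest.raises(ValueError):
            tf.evaluate_recovery(tf.ResponseNetwork(), tf.GroundTruth())


class TestMaxConsecutiveOverlap:
    def _rn(self, pairs):
        genes = {g for p in pairs for g in p}
        return tf.ResponseNetwork(
            nodes=[tf.ResponseNode(g, "NOD", 1.0) for g in genes],
            edges=[tf.ResponseEdge(u, v, tf.Directionality.UNIDIRECTIONAL,
                                   1.0, 0.9) for u, v in pairs])

    def test_hand_counts(self):
        rn = self._rn([("A", "B"), ("B", "C")])
        assert tf.max_consecutive_overlap(
            rn, {("A", "B"), ("B", "C"), ("C", "D")}) == 2
        assert tf.max_consecutive_overlap(rn, {("X", "Y")}) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_networkx_longest_simple_path(self, seed):
        """Independent oracle: enumerate all simple paths of the intersection
        graph with networkx and take the longest."""
        import networkx as nx

        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(8)]
        pairs = {(nodes[int(i)], nodes[int(j)])
                 for i, j in rng.integers(0, 8, size=(12, 2)) if i != j}
        ref = {(nodes[int(i)], nodes[int(j)])
               for i, j in rng.integers(0, 8, size=(12, 2)) if i != j}
        rn = self._rn(sorted(pairs))

        common = pairs & ref
        expected = 0
        if common:
            g = nx.DiGraph(sorted(common))
            for s in g.nodes:
                for t in g.nodes:
                    if s == t:
                        continue
                    for path in nx.all_simple_paths(g, s, t):
                        expected = max(expected, len(path) - 1)
        assert tf.max_consecutive_overlap(rn, ref) == expected
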