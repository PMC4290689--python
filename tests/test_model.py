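"""Flow-graph construction and LP encoding."""

import math

import pytest

import tempoflow as tf
from tempoflow.model import SINK, SOURCE, ArcKind


class TestArcCost:
    @pytest.mark.parametrize("weight,expected", [
        (1.0, 0.0),
        (0.5, math.log(2)),
        (1e-9, -math.log(1e-6)),  # floor clamps pathological weights
    ])
    def test_negative_log_with_floor(self, weight, expected):
        assert tf.arc_cost(weight) == pytest.approx(expected)

    def test_monotone_decreasing_in_weight(self):
        costs = [tf.arc_cost(w) for w in (0.1, 0.3, 0.6, 0.9, 1.0)]
        assert costs == sorted(costs, reverse=True)
        assert costs[-1] == 0.0

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_out_of_range_weight_rejected(self, bad):
        with pytest.raises(ValueError):
            tf.arc_cost(bad)


class TestNodeCapacity:
    @pytest.mark.parametrize("group,gene,expected", [
        ({"A": 1.0, "B": 1.0}, "A", 0.5),
        ({"A": 3.0, "B": 1.0}, "A", 0.75),
        ({"A": 2.0}, "A", 1.0),
    ])
    def test_group_normalized_scores(self, group, gene, expected):
        assert tf.node_capacity(gene, group) == pytest.approx(expected)

    def test_capacities_sum_to_one_per_group(self, small_instance):
        _, part, _ = small_instance
        for group in (part.early, part.intermediate, part.late):
            total = sum(tf.node_capacity(g, group) for g in group)
            assert total == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            tf.node_capacity("A", {})


class TestBuildFlowGraph:
    def test_three_gene_chain_arc_enumeration(self, tiny_net, tiny_part,
                                              tiny_params):
        g = tf.build_flow_graph(tiny_net, tiny_part, tiny_params)
        arcs = {(a.tail, a.head): a for a in g.arcs}
        # 2 ordered interactions x 2 layers + source + transit + sink + return
        assert len(g.arcs) == 8
        assert (SOURCE, "A::A") in arcs
        assert ("B::A", "B::B") in arcs  # transit
        assert ("C::B", SINK) in arcs
        assert (SINK, SOURCE) in arcs
        assert ("A::A", "B::A") in arcs and ("A::B", "B::B") in arcs
        assert ("B::A", "C::A") in arcs and ("B::B", "C::B") in arcs
        assert arcs[(SOURCE, "A::A")].capacity == 1.0
        assert math.isinf(arcs[(SINK, SOURCE)].capacity)

    def test_bidirectional_edge_yields_four_interaction_arcs(self, tiny_params):
        net = tf.InteractionNetwork()
        net.add(tf.Interaction("A", "B", tf.Directionality.BIDIRECTIONAL, 0.8))
        net.add(tf.Interaction("B", "A", tf.Directionality.BIDIRECTIONAL, 0.8))
        net.add(tf.Interaction("B", "C", tf.Directionality.UNIDIRECTIONAL, 0.9))
        part = tf.GeneGroupPartition(early={"A": 1.0}, intermediate={"B": 1.0},
                                     late={"C": 1.0})
        g = tf.build_flow_graph(net, part, tiny_params)
        inter = [a for a in g.arcs
                 if a.kind in (ArcKind.INTERACTION_A, ArcKind.INTERACTION_B)
                 and {a.tail.split("::")[0], a.head.split("::")[0]} == {"A", "B"}]
        assert len(inter) == 4

    def test_no_arcs_cross_layers_except_transit(self, small_instance):
        net, part, _ = small_instance
        g = tf.build_flow_graph(net, part, tf.LPParameters(1.0, 1.0))
        for a in g.arcs:
            if a.kind in (ArcKind.INTERACTION_A, ArcKind.INTERACTION_B):
                assert a.tail.endswith(a.head[-3:])  # same ::A / ::B suffix
            elif a.kind is ArcKind.TRANSIT_ARC:
                assert a.tail.endswith("::A") and a.head.endswith("::B")
                gene = a.tail.rsplit("::", 1)[0]
                assert gene in part.intermediate

    def test_disconnected_problem_is_fatal(self, tiny_params):
        net = tf.InteractionNetwork()
        net.add(tf.Interaction("B", "C", tf.Directionality.UNIDIRECTIONAL, 0.9))
        net.add(tf.Interaction("C", "A", tf.Directionality.UNIDIRECTIONAL, 0.9))
        part = tf.GeneGroupPartition(early={"A": 1.0}, intermediate={"B": 1.0},
                                     late={"C": 1.0})
        with pytest.raises(tf.InputError, match="disconnected"):
            tf.build_flow_graph(net, part, tiny_params)

    def test_dead_end_early_gene_still_builds(self, tiny_net, tiny_params):
        # D is early but has no edges in the network: graph builds, D's
        # source arc simply cannot carry flow
        part = tf.GeneGroupPartition(early={"A": 1.0, "D": 1.0},
                                     intermediate={"B": 1.0}, late={"C": 1.0})
        part_restricted = tf.validate_partition(
            {tf.ScoredGene("A", 1.0), tf.ScoredGene("D", 1.0)},
            {tf.ScoredGene("B", 1.0)}, {tf.ScoredGene("C", 1.0)}, tiny_net)
        g = tf.build_flow_graph(tiny_net, part_restricted, tiny_params)
        assert g is not None


class TestFormulateLP:
    def test_incidence_shape(self, tiny_net, tiny_part, tiny_params):
        g = tf.build_flow_graph(tiny_net, tiny_part, tiny_params)
        prob = tf.formulate_lp(g)
        assert prob.a_eq.shape == (len(g.nodes), len(g.arcs))
        assert len(prob.c) == len(g.arcs)
        # incidence: every column has exactly one +1 and one -1
        col_sums = prob.a_eq.toarray().sum(axis=0)
        assert (abs(col_sums) < 1e-12).all()

    def test_zero_gammas_give_zero_flow(self, tiny_net, tiny_part):
        params = tf.LPParameters(gamma1=0.0, gamma2=0.0)
        g = tf.build_flow_graph(tiny_net, tiny_part, params)
        sol = tf.solve(tf.formulate_lp(g))
        assert sol.status is tf.SolveStatus.OPTIMAL
        assert sol.objective == pytest.approx(0.0, abs=1e-9)
        assert abs(sol.flows).max() == pytest.approx(0.0, abs=1e-9)

    def test_single_path_reward_drives_unit_flow(self, tiny_result, tiny_params):
        # one reliable path, capacities all 1: optimum saturates the path and
        # the objective is exactly -(gamma1 + gamma2)
        sol = tiny_result.solution
        assert sol.objective == pytest.approx(
            -(tiny_params.gamma1 + tiny_params.gamma2))
        assert tf.conservation_residual(sol, tiny_result.problem) < 1e-8

    def test_rewards_on_source_and_transit_only(self, tiny_net, tiny_part,
                                                tiny_params):
        g = tf.build_flow_graph(tiny_net, tiny_part, tiny_params)
        prob = tf.formulate_lp(g)
        for coef, arc in zip(prob.c, g.arcs):
            if arc.kind is ArcKind.SOURCE_ARC:
                assert coef == -tiny_params.gamma1
            elif arc.kind is ArcKind.TRANSIT_ARC:
                assert coef == -tiny_params.gamma2
            else:
                assert coef >= 0.0
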