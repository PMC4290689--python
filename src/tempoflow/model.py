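"""Time-layered minimum-cost-flow model of the temporal response network.

The temporal-path constraint — flow must run from an initial-response gene to
a late effector *via* an intermediate regulator — is encoded structurally by
replicating every gene into two layers, A and B. Interaction arcs exist within
each layer only; the sole arcs crossing layers are the transit arcs
(g, A) -> (g, B) owned by intermediate-group genes. Source arcs attach the
artificial source S to early genes in layer A, sink arcs attach late genes in
layer B to the artificial sink T, and a costless unbounded return arc T -> S
closes the circulation, so plain flow conservation holds at every node.
Consequently every source-to-sink path crosses exactly one transit arc, which
is the time-dependent ordering early -> intermediate -> late.

Objective:  minimize  sum_a cost_a f_a  -  gamma1 * sum_source f  -  gamma2 * sum_transit f

with cost_a = -log(weight_a) for interaction arcs (multiplicative path
reliability becomes additive cost) and cost 0 on all artificial arcs. The
gammas decide how much flow — hence how many early genes and intermediate
regulators — is worth including.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy import sparse

from .datatypes import (
    GeneGroupPartition,
    InputError,
    InteractionNetwork,
    LPParameters,
)

SOURCE = "__S__"
SINK = "__T__"


class ArcKind(IntEnum):
    """Arc roles; the integer order defines the canonical variable ordering."""

    SOURCE_ARC = 0
    INTERACTION_A = 1
    INTERACTION_B = 2
    TRANSIT_ARC = 3
    SINK_ARC = 4
    RETURN_ARC = 5


@dataclass(frozen=True)
class FlowArc:
    tail: str
    head: str
    capacity: float  # math.inf for the return arc
    cost: float
    kind: ArcKind
    #: for interaction arcs: the ordered gene pair this arc instantiates
    gene_pair: tuple[str, str] | None = None


@dataclass
class FlowGraph:
    nodes: list[str]
    arcs: list[FlowArc]
    partition: GeneGroupPartition
    params: LPParameters
    network: InteractionNetwork

    @property
    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def arcs_of_kind(self, kind: ArcKind) -> list[int]:
        return [i for i, a in enumerate(self.arcs) if a.kind is kind]


@dataclass
class LPProblem:
    """Continuous LP encoding: min c.f  s.t.  A_eq f = 0,  0 <= f <= capacity."""

    c: np.ndarray
    a_eq: sparse.csr_matrix
    bounds: list[tuple[float, float | None]]
    var_names: list[str]
    node_names: list[str]
    graph: FlowGraph


def layer_node(gene: str, layer: str) -> str:
    return f"{gene}::{layer}"


def arc_cost(weight: float, weight_floor: float = 1e-6) -> float:
    """Additive arc cost -log(weight) of one reliability-weighted interaction.

    The floor clamps pathological near-zero weights so costs stay finite.
    """
    if not (0 < weight <= 1):
        raise ValueError(f"weight must be in (0, 1], got {weight!r}")
    return -math.log(max(weight, weight_floor)) + 0.0  # +0.0 normalizes -0.0


def node_capacity(gene: str, group: dict[str, float]) -> float:
    """Group-normalized score: capacity of a gene's terminal/transit arc.

    Capacities over a group sum to 1, which keeps gamma values comparable
    across datasets of different size and score scale.
    """
    if not group:
        raise ValueError("empty gene group")
    total = sum(group.values())
    if not total > 0:
        raise ValueError("group scores must sum to a positive value")
    if gene not in group:
        raise KeyError(gene)
    return group[gene] / total


def build_flow_graph(
    net: InteractionNetwork,
    part: GeneGroupPartition,
    params: LPParameters,
) -> FlowGraph:
    """Instantiate the two-layer flow graph for a validated network/partition."""
    genes = sorted(net.genes)
    has_out = {s for s, _ in net.ordered_pairs}
    has_in = {t for _, t in net.ordered_pairs}
    if not any(g in has_out for g in part.early):
        raise InputError("disconnected problem: no early gene has an outgoing interaction")
    if not any(g in has_in for g in part.late):
        raise InputError("disconnected problem: no late gene has an incoming interaction")

    nodes = [SOURCE, SINK]
    for g in genes:
        nodes.append(layer_node(g, "A"))
        nodes.append(layer_node(g, "B"))

    arcs: list[FlowArc] = []
    for g in sorted(part.early):
        arcs.append(
            FlowArc(SOURCE, layer_node(g, "A"), node_capacity(g, part.early), 0.0,
                    ArcKind.SOURCE_ARC)
        )
    for inter in sorted(net, key=lambda i: (i.source, i.target)):
        cost = arc_cost(inter.weight, params.weight_floor)
        pair = (inter.source, inter.target)
        arcs.append(
            FlowArc(layer_node(inter.source, "A"), layer_node(inter.target, "A"),
                    params.interaction_capacity, cost, ArcKind.INTERACTION_A, pair)
        )
    for inter in sorted(net, key=lambda i: (i.source, i.target)):
        cost = arc_cost(inter.weight, params.weight_floor)
        pair = (inter.source, inter.target)
        arcs.append(
            FlowArc(layer_node(inter.source, "B"), layer_node(inter.target, "B"),
                    params.interaction_capacity, cost, ArcKind.INTERACTION_B, pair)
        )
    for g in sorted(part.intermediate):
        arcs.append(
            FlowArc(layer_node(g, "A"), layer_node(g, "B"),
                    node_capacity(g, part.intermediate), 0.0, ArcKind.TRANSIT_ARC)
        )
    for g in sorted(part.late):
        arcs.append(
            FlowArc(layer_node(g, "B"), SINK, node_capacity(g, part.late), 0.0,
                    ArcKind.SINK_ARC)
        )
    arcs.append(FlowArc(SINK, SOURCE, math.inf, 0.0, ArcKind.RETURN_ARC))

    # canonical order: kind, then tail, then head
    arcs.sort(key=lambda a: (int(a.kind), a.tail, a.head))
    return FlowGraph(nodes=nodes, arcs=arcs, partition=part, params=params,
                     network=net)


def _var_name(i: int) -> str:
    return f"x{i}"


def formulate_lp(graph: FlowGraph, params: LPParameters | None = None) -> LPProblem:
    """Encode the flow graph as a linear program.

    One variable per arc, bounded by [0, capacity]; one flow-conservation
    equality per node (the return arc closes S and T). Always feasible: the
    all-zero flow satisfies every constraint.
    """
    params = params or graph.params
    n_nodes = len(graph.nodes)
    n_arcs = len(graph.arcs)
    idx = graph.node_index

    c = np.zeros(n_arcs)
    bounds: list[tuple[float, float | None]] = []
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for j, arc in enumerate(graph.arcs):
        if arc.kind is ArcKind.SOURCE_ARC:
            c[j] = -params.gamma1
        elif arc.kind is ArcKind.TRANSIT_ARC:
            c[j] = -params.gamma2
        else:
            c[j] = arc.cost
        ub = None if math.isinf(arc.capacity) else arc.capacity
        bounds.append((0.0, ub))
        rows += [idx[arc.tail], idx[arc.head]]
        cols += [j, j]
        vals += [1.0, -1.0]  # outflow positive, inflow negative; conservation = 0

    a_eq = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_nodes, n_arcs), dtype=float
    )
    names = [_var_name(j) for j in range(n_arcs)]
    return LPProblem(c=c, a_eq=a_eq, bounds=bounds, var_names=names,
                     node_names=list(graph.nodes), graph=graph)
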