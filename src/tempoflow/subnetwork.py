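"""Reduction of the solved layered flow to a gene-level response network.

Layer bookkeeping disappears here: the two layer copies of an ordered gene
pair are summed into one edge flow, and a gene's importance is its total
inflow (source + interaction arcs) across both copies. Transit arcs are
internal to a gene and are not counted, so node flows stay conserved with
edge flows. Nodes are typed by input-group membership: SRC (initial response
genes), INT (intermediate regulators), SNK (late effectors) and NOD —
predicted genes with no measured expression change, the transient regulators
the method exists to surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datatypes import Directionality, GeneGroupPartition
from .model import ArcKind, FlowGraph
from .solver import FlowSolution, SolveStatus


@dataclass(frozen=True)
class ResponseNode:
    gene: str
    node_type: str  # SRC | INT | SNK | NOD
    flow: float


@dataclass(frozen=True)
class ResponseEdge:
    source: str
    target: str
    interaction_type: Directionality
    flow: float
    weight: float


@dataclass
class ResponseNetwork:
    nodes: list[ResponseNode] = field(default_factory=list)
    edges: list[ResponseEdge] = field(default_factory=list)

    @property
    def node_genes(self) -> set[str]:
        return {n.gene for n in self.nodes}

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def node_type_of(self, gene: str) -> str | None:
        for n in self.nodes:
            if n.gene == gene:
                return n.node_type
        return None

    def is_empty(self) -> bool:
        return not self.nodes and not self.edges


NODE_TYPES = ("SRC", "INT", "SNK", "NOD")


def _gene_of(layer_name: str) -> str:
    return layer_name.rsplit("::", 1)[0]


def node_type_for(gene: str, part: GeneGroupPartition) -> str:
    group = part.group_of(gene)
    return {"early": "SRC", "intermediate": "INT", "late": "SNK", None: "NOD"}[group]


def extract_subnetwork(
    solution: FlowSolution, graph: FlowGraph, tol: float | None = None
) -> ResponseNetwork:
    """Collapse layers of an optimal flow into a typed gene-level network.

    Edge flow of an ordered pair is the sum of its two layer arcs' flows;
    node flow is the gene's total inflow from source and interaction arcs.
    Entries at or below `tol` are dropped (the LP's noise floor).
    """
    if solution.status is not SolveStatus.OPTIMAL:
        raise ValueError("cannot extract a subnetwork from a non-optimal solution")
    tol = graph.params.flow_tolerance if tol is None else tol

    edge_flow: dict[tuple[str, str], float] = {}
    edge_meta: dict[tuple[str, str], tuple[Directionality, float]] = {}
    node_inflow: dict[str, float] = {}

    for arc, f in zip(graph.arcs, solution.flows):
        if arc.kind in (ArcKind.INTERACTION_A, ArcKind.INTERACTION_B):
            pair = arc.gene_pair
            edge_flow[pair] = edge_flow.get(pair, 0.0) + f
            if f > 0:
                node_inflow[pair[1]] = node_inflow.get(pair[1], 0.0) + f
        elif arc.kind is ArcKind.SOURCE_ARC:
            g = _gene_of(arc.head)
            node_inflow[g] = node_inflow.get(g, 0.0) + f

    part = graph.partition
    edges = []
    for pair in sorted(edge_flow):
        f = edge_flow[pair]
        if f <= tol:
            continue
        inter = graph.network.get(*pair)
        edges.append(
            ResponseEdge(source=pair[0], target=pair[1],
                         interaction_type=inter.directionality, flow=f,
                         weight=inter.weight)
        )

    keep_genes = {e.source for e in edges} | {e.target for e in edges}
    keep_genes |= {g for g, f in node_inflow.items() if f > tol}
    nodes = [
        ResponseNode(gene=g, node_type=node_type_for(g, part),
                     flow=node_inflow.get(g, 0.0))
        for g in sorted(keep_genes)
        if node_inflow.get(g, 0.0) > tol
    ]
    kept = {n.gene for n in nodes}
    edges = [e for e in edges if e.source in kept and e.target in kept]
    return ResponseNetwork(nodes=nodes, edges=edges)


def assign_node_types(rn: ResponseNetwork, part: GeneGroupPartition) -> ResponseNetwork:
    """Re-derive every node's type from group membership.

    SRC/INT/SNK mark members of the early/intermediate/late input groups;
    everything else carrying flow is NOD. Extraction already types nodes this
    way; this is the explicit re-typing used when a partition is revised.
    """
    nodes = [
        ResponseNode(gene=n.gene, node_type=node_type_for(n.gene, part), flow=n.flow)
        for n in rn.nodes
    ]
    return ResponseNetwork(nodes=nodes, edges=list(rn.edges))


def count_low_reliability_edges(rn: ResponseNetwork, threshold: float = 0.3) -> int:
    """Edges in the predicted network whose reliability is below `threshold`.

    "Low reliability" has no canonical cutoff; 0.3 is this package's default
    and is configurable wherever the count is used.
    """
    return sum(1 for e in rn.edges if e.weight < threshold)
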