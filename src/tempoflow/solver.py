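"""LP solving and flow-path decomposition.

The LP is handed to HiGHS through :func:`scipy.optimize.linprog`, which is
deterministic for a fixed problem and solver options. The decomposition
routine strips source-to-sink paths greedily from a solved flow and is used
both for reporting and to verify the temporal-path property (every path
crosses exactly one transit arc).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import linprog

from .model import SINK, SOURCE, ArcKind, FlowGraph, LPProblem


class SolveStatus(str, Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    ERROR = "error"


@dataclass
class FlowSolution:
    flows: np.ndarray  # one entry per arc, canonical order
    objective: float
    status: SolveStatus
    message: str = ""

    def flow_of_kind(self, graph: FlowGraph, kind: ArcKind) -> float:
        return float(sum(self.flows[i] for i in graph.arcs_of_kind(kind)))


@dataclass
class FlowPath:
    nodes: list[str]
    amount: float

    def arcs(self) -> list[tuple[str, str]]:
        return list(zip(self.nodes, self.nodes[1:]))


@dataclass
class Decomposition:
    paths: list[FlowPath]
    cycle_flow: float = 0.0
    cycles: list[FlowPath] = field(default_factory=list)
    #: sub-tolerance residual discarded at dead ends (solver noise)
    stranded: float = 0.0


def solve(problem: LPProblem, method: str = "highs") -> FlowSolution:
    """Solve the min-cost-flow LP; never raises on solver-reported failure."""
    try:
        res = linprog(
            c=problem.c,
            A_eq=problem.a_eq,
            b_eq=np.zeros(problem.a_eq.shape[0]),
            bounds=problem.bounds,
            method=method,
        )
    except Exception as exc:  # pragma: no cover - defensive
        return FlowSolution(
            flows=np.zeros(len(problem.c)), objective=float("nan"),
            status=SolveStatus.ERROR, message=str(exc),
        )
    if res.status == 0:
        flows = np.asarray(res.x, dtype=float)
        flows[flows < 0] = 0.0  # clip solver noise below the lower bound
        return FlowSolution(flows=flows, objective=float(res.fun),
                            status=SolveStatus.OPTIMAL, message=res.message)
    status = {2: SolveStatus.INFEASIBLE, 3: SolveStatus.UNBOUNDED}.get(
        res.status, SolveStatus.ERROR
    )
    return FlowSolution(flows=np.zeros(len(problem.c)), objective=float("nan"),
                        status=status, message=res.message)


def decompose_flow(
    solution: FlowSolution, graph: FlowGraph, tol: float | None = None
) -> Decomposition:
    """Greedy path-stripping of a solved flow into S -> T paths (+ cycles).

    Repeatedly traces a path from the source, at each branch taking the arc
    with the largest residual flow (ties broken by lexicographically smaller
    head), subtracts the bottleneck, and stops when no residual flow leaves
    the source. Residual circulation that never touches the source — possible
    in degenerate optima on zero-cost cycles — is stripped separately and
    reported as cycles, not paths.
    """
    if solution.status is not SolveStatus.OPTIMAL:
        raise ValueError("can only decompose an optimal solution")
    tol = graph.params.flow_tolerance if tol is None else tol

    residual = solution.flows.copy()
    out_arcs: dict[str, list[int]] = {}
    for j, arc in enumerate(graph.arcs):
        if arc.kind is ArcKind.RETURN_ARC:
            residual[j] = 0.0  # the return arc closes the circulation; not a path arc
            continue
        out_arcs.setdefault(arc.tail, []).append(j)

    def best_out(node: str) -> int | None:
        cands = [j for j in out_arcs.get(node, []) if residual[j] > tol]
        if not cands:
            return None
        return min(cands, key=lambda j: (-residual[j], graph.arcs[j].head))

    paths: list[FlowPath] = []
    cycles: list[FlowPath] = []
    cycle_flow = 0.0
    stranded = 0.0

    def strip(start: str, as_path: bool) -> None:
        """Trace one walk from `start`; strip a path (S to T), a cycle, or —
        at a dead end — the walk's bottleneck as stranded noise. Every call
        drives at least one arc's residual to zero, so stripping terminates.
        """
        nonlocal cycle_flow, stranded
        node = start
        walk_nodes = [start]
        walk_arcs: list[int] = []
        seen_at = {start: 0}
        while node != SINK:
            j = best_out(node)
            if j is None:
                # tolerance crumbs: conservation holds in the solution, so a
                # genuine dead end can only strand sub-tolerance residue
                if walk_arcs:
                    amt = min(residual[j2] for j2 in walk_arcs)
                    for j2 in walk_arcs:
                        residual[j2] -= amt
                    stranded += amt
                return
            arc = graph.arcs[j]
            walk_arcs.append(j)
            node = arc.head
            if node in seen_at:  # cycle in the residual flow: strip it
                k = seen_at[node]
                cyc_arcs = walk_arcs[k:]
                amt = min(residual[j2] for j2 in cyc_arcs)
                for j2 in cyc_arcs:
                    residual[j2] -= amt
                cycles.append(FlowPath(nodes=walk_nodes[k:] + [node], amount=amt))
                cycle_flow += amt
                return
            seen_at[node] = len(walk_nodes)
            walk_nodes.append(node)
        amt = min(residual[j2] for j2 in walk_arcs)
        for j2 in walk_arcs:
            residual[j2] -= amt
        if as_path and start == SOURCE:
            paths.append(FlowPath(nodes=walk_nodes, amount=amt))
        else:  # walk to T not anchored at S: degenerate residue, not a path
            stranded += amt

    while best_out(SOURCE) is not None:
        strip(SOURCE, as_path=True)

    # strip any remaining circulation not reachable from S
    for j0 in range(len(residual)):
        while residual[j0] > tol:
            strip(graph.arcs[j0].tail, as_path=False)

    return Decomposition(paths=paths, cycle_flow=cycle_flow, cycles=cycles,
                         stranded=stranded)


def conservation_residual(solution: FlowSolution, problem: LPProblem) -> float:
    """Max |inflow - outflow| over all nodes; ~0 for a valid solution."""
    return float(np.abs(problem.a_eq @ solution.flows).max())


def capacity_violation(solution: FlowSolution, problem: LPProblem) -> float:
    """Max amount by which any arc flow exceeds its capacity (0 if none)."""
    worst = 0.0
    for f, (lo, hi) in zip(solution.flows, problem.bounds):
        worst = max(worst, lo - f)
        if hi is not None:
            worst = max(worst, f - hi)
    return float(max(worst, 0.0))
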