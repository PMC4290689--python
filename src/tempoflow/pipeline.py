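"""End-to-end single-run pipeline: read, validate, build, solve, extract, write.

This is the programmatic equivalent of one command-line run and the unit of
work the grid search repeats per (gamma1, gamma2) cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .datatypes import (
    GeneGroupPartition,
    InputError,
    InteractionNetwork,
    LogCategory,
    LPParameters,
    ValidationLog,
)
from . import io as tio
from .model import FlowGraph, LPProblem, build_flow_graph, formulate_lp
from .solver import FlowSolution, SolveStatus, solve
from .subnetwork import ResponseNetwork, extract_subnetwork


@dataclass
class RunResult:
    network: InteractionNetwork
    partition: GeneGroupPartition
    graph: FlowGraph
    problem: LPProblem
    solution: FlowSolution
    response: ResponseNetwork
    log: ValidationLog


def run_on_data(
    net: InteractionNetwork,
    part: GeneGroupPartition,
    params: LPParameters,
    log: ValidationLog | None = None,
) -> RunResult:
    """Run the core method on in-memory inputs (no file I/O)."""
    log = log if log is not None else ValidationLog()
    graph = build_flow_graph(net, part, params)
    problem = formulate_lp(graph)
    solution = solve(problem)
    log.record(LogCategory.INFO,
               f"solver status: {solution.status.value}, "
               f"objective: {solution.objective!r}")
    if solution.status is not SolveStatus.OPTIMAL:
        raise InputError(f"solver failed: {solution.status.value} "
                         f"({solution.message})")
    rn = extract_subnetwork(solution, graph)
    return RunResult(network=net, partition=part, graph=graph, problem=problem,
                     solution=solution, response=rn, log=log)


def run_single(
    early_path: str | Path,
    intermediate_path: str | Path,
    late_path: str | Path,
    network_path: str | Path,
    params: LPParameters,
    outdir: str | Path,
) -> RunResult:
    """Full file-to-file run; writes the standard artifact set into `outdir`."""
    log = ValidationLog()
    early = tio.read_gene_list(early_path, "early", log)
    intermediate = tio.read_gene_list(intermediate_path, "intermediate", log)
    late = tio.read_gene_list(late_path, "late", log)
    net, _ = tio.read_network(network_path, log)
    part = tio.validate_partition(early, intermediate, late, net, log)

    result = run_on_data(net, part, params, log)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_response_network(result.response, outdir, log)
    tio.write_lp_artifacts(result.problem, result.solution, outdir, log)
    tio.write_log(log, outdir)
    return result
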