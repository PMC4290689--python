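"""Readers and writers for the tool's tab-delimited conventions.

Inputs: three 2-column gene lists (gene, score) and a 4-column network file
(gene1, gene2, directionality, reliability). Outputs: Cytoscape-importable
node/edge attribute tables, the LP formulation in CPLEX LP text, the final
arc list, the raw solver dump and a run log. All files are UTF-8 with LF
endings; flows print with six decimals so repeated runs are byte-stable.

Validation philosophy: malformed records are skipped and logged, never
silently dropped; empty results after filtering are fatal. Gene identifiers
match case-sensitively — silently merging species naming conventions is
worse than a logged miss.
"""

from __future__ import annotations

import math
from pathlib import Path

from .datatypes import (
    DIRECTIONALITY_TOKENS,
    Directionality,
    GeneGroupPartition,
    InputError,
    Interaction,
    InteractionNetwork,
    LogCategory,
    ScoredGene,
    ValidationLog,
)
from .lpformat import export_lp
from .model import LPProblem
from .solver import FlowSolution, SolveStatus
from .subnetwork import ResponseNetwork


def _parse_score(token: str) -> float | None:
    if "," in token:  # comma thousands separators are rejected, not guessed at
        return None
    try:
        value = float(token)
    except ValueError:
        return None
    if not math.isfinite(value):
        return None
    return value


def read_gene_list(
    path: str | Path, label: str, log: ValidationLog | None = None
) -> set[ScoredGene]:
    """Read one scored gene list (gene<TAB>score per line).

    Non-numeric or non-positive scores are skipped and logged; duplicate gene
    names keep the maximum score (order-independent) and log a duplicate
    event. Zero valid entries is fatal.
    """
    log = log if log is not None else ValidationLog()
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read gene list {path}: {exc}") from exc

    best: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0]:
            log.record(LogCategory.MALFORMED_LINE, f"{label}:{lineno}: {raw!r}")
            continue
        name, score_tok = parts[0], parts[1]
        score = _parse_score(score_tok)
        if score is None or score <= 0:
            log.record(LogCategory.BAD_GENE_SCORE,
                       f"{label}:{lineno}: gene {name} score {score_tok!r}")
            continue
        if name in best:
            log.record(LogCategory.DUPLICATE_GENE,
                       f"{label}:{lineno}: duplicate gene {name}, keeping max score")
            best[name] = max(best[name], score)
        else:
            best[name] = score
    if not best:
        raise InputError(f"gene list {path} ({label}) has no valid entries")
    return {ScoredGene(n, s) for n, s in best.items()}


def read_network(
    path: str | Path, log: ValidationLog | None = None
) -> tuple[InteractionNetwork, ValidationLog]:
    """Read the 4-column weighted network file.

    Bidirectional records expand to two ordered arcs. Weights outside (0, 1],
    self-loops, unknown directionality tokens and malformed lines are skipped
    and logged; duplicate ordered pairs keep the maximum weight and are
    logged as ignored duplicates. An empty network after filtering is fatal.
    """
    log = log if log is not None else ValidationLog()
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read network {path}: {exc}") from exc

    net = InteractionNetwork()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4 or not parts[0] or not parts[1]:
            log.record(LogCategory.MALFORMED_LINE, f"network:{lineno}: {raw!r}")
            continue
        g1, g2, dir_tok, w_tok = parts
        direction = DIRECTIONALITY_TOKENS.get(dir_tok.strip().lower())
        if direction is None:
            log.record(LogCategory.BAD_DIRECTIONALITY,
                       f"network:{lineno}: unknown token {dir_tok!r}")
            continue
        weight = _parse_score(w_tok)
        if weight is None or not (0 < weight <= 1):
            log.record(LogCategory.BAD_EDGE_SCORE,
                       f"network:{lineno}: {g1}-{g2} weight {w_tok!r}")
            continue
        if g1 == g2:
            log.record(LogCategory.SELF_LOOP, f"network:{lineno}: {g1}")
            continue
        pairs = [(g1, g2)]
        if direction is Directionality.BIDIRECTIONAL:
            pairs.append((g2, g1))
        duplicate = False
        for s, t in pairs:
            existing = net.get(s, t)
            if existing is not None:
                duplicate = True
            net.add(Interaction(source=s, target=t, directionality=direction,
                                weight=weight))
        if duplicate:
            log.record(LogCategory.DUPLICATE_EDGE,
                       f"network:{lineno}: duplicate edge {g1}-{g2} ignored "
                       "(max weight kept)")
    if len(net) == 0:
        raise InputError(f"network {path} has no valid interactions")
    return net, log


def validate_partition(
    early: set[ScoredGene],
    intermediate: set[ScoredGene],
    late: set[ScoredGene],
    net: InteractionNetwork,
    log: ValidationLog | None = None,
) -> GeneGroupPartition:
    """Check mutual exclusivity and restrict the groups to network genes.

    Overlapping groups are fatal (offenders named). Genes absent from the
    network are logged and removed; a group emptied by the restriction is
    fatal.
    """
    log = log if log is not None else ValidationLog()
    sets = {
        "early": {g.name: g.score for g in early},
        "intermediate": {g.name: g.score for g in intermediate},
        "late": {g.name: g.score for g in late},
    }
    names = list(sets.values())
    overlap = (
        (set(names[0]) & set(names[1]))
        | (set(names[0]) & set(names[2]))
        | (set(names[1]) & set(names[2]))
    )
    if overlap:
        raise InputError(
            "gene groups overlap (groups must be mutually exclusive): "
            + ", ".join(sorted(overlap))
        )
    net_genes = net.genes
    restricted: dict[str, dict[str, float]] = {}
    for label, group in sets.items():
        kept = {}
        for name, score in group.items():
            if name in net_genes:
                kept[name] = score
            else:
                log.record(LogCategory.GENE_NOT_IN_NETWORK, f"{label}: {name}")
        if not kept:
            raise InputError(f"{label} group is empty after removing genes "
                             "absent from the network")
        restricted[label] = kept
    return GeneGroupPartition(early=restricted["early"],
                              intermediate=restricted["intermediate"],
                              late=restricted["late"])


def write_gene_list(genes: dict[str, float] | set[ScoredGene], path: str | Path) -> None:
    """Write a 2-column gene list in the input format (sorted, stable)."""
    if isinstance(genes, set):
        genes = {g.name: g.score for g in genes}
    lines = [f"{name}\t{format(score, '.6f')}" for name, score in sorted(genes.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write a network in the 4-column input format (one line per record)."""
    lines = []
    for inter in net.undirected_interactions():
        lines.append(
            f"{inter.source}\t{inter.target}\t{inter.directionality.value}\t"
            f"{format(inter.weight, '.6f')}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_response_network(
    rn: ResponseNetwork, outdir: str | Path, log: ValidationLog | None = None
) -> tuple[Path, Path]:
    """Write nodes.txt and edges.txt attribute tables (Cytoscape-importable).

    Deterministic ordering (flow descending, then name) and fixed 6-decimal
    flow formatting make the files byte-stable for a given network.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if rn.is_empty() and log is not None:
        log.record(LogCategory.WARNING, "predicted response network is empty")

    node_lines = ["gene\ttype\tflow"]
    for n in sorted(rn.nodes, key=lambda n: (-n.flow, n.gene)):
        node_lines.append(f"{n.gene}\t{n.node_type}\t{format(n.flow, '.6f')}")
    nodes_path = outdir / "nodes.txt"
    nodes_path.write_text("\n".join(node_lines) + "\n", encoding="utf-8")

    edge_lines = ["source\ttarget\tinteraction_type\tflow\tweight"]
    for e in sorted(rn.edges, key=lambda e: (-e.flow, e.source, e.target)):
        edge_lines.append(
            f"{e.source}\t{e.target}\t{e.interaction_type.value}\t"
            f"{format(e.flow, '.6f')}\t{format(e.weight, '.6f')}"
        )
    edges_path = outdir / "edges.txt"
    edges_path.write_text("\n".join(edge_lines) + "\n", encoding="utf-8")
    return nodes_path, edges_path


def write_lp_artifacts(
    problem: LPProblem,
    solution: FlowSolution | None,
    outdir: str | Path,
    log: ValidationLog | None = None,
) -> None:
    """Write problem.lp (CPLEX LP text), arcs.txt and solution.raw.

    The arc list maps LP variable names back to graph arcs with their cost
    and capacity. On solver failure the solution file is omitted and the
    omission logged.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "problem.lp").write_text(export_lp(problem), encoding="utf-8")

    arc_lines = ["variable\tkind\ttail\thead\tcost\tcapacity"]
    for name, arc in zip(problem.var_names, problem.graph.arcs):
        cap = "inf" if math.isinf(arc.capacity) else format(arc.capacity, ".6f")
        arc_lines.append(
            f"{name}\t{arc.kind.name.lower()}\t{arc.tail}\t{arc.head}\t"
            f"{format(arc.cost, '.6f')}\t{cap}"
        )
    (outdir / "arcs.txt").write_text("\n".join(arc_lines) + "\n", encoding="utf-8")

    if solution is not None and solution.status is SolveStatus.OPTIMAL:
        sol_lines = [
            f"{name}\t{format(f, '.12g')}"
            for name, f in zip(problem.var_names, solution.flows)
        ]
        (outdir / "solution.raw").write_text("\n".join(sol_lines) + "\n",
                                             encoding="utf-8")
    elif log is not None:
        status = solution.status.value if solution is not None else "absent"
        log.record(LogCategory.WARNING,
                   f"no solution written (solver status: {status})")


def write_log(log: ValidationLog, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "run.log"
    path.write_text("\n".join(log.lines()) + ("\n" if log.events else ""),
                    encoding="utf-8")
    return path
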