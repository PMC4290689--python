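"""Iterative grid mode over (gamma1, gamma2) with optimal-cell selection.

One full pipeline run per parameter combination, each in its own
subdirectory; a statistics table summarizes how many input-group genes and
how many low-reliability edges each predicted network contains. The optimal
cell is the one including the most input-group genes, breaking ties by the
fewest low-reliability edges, then by the smallest (gamma1, gamma2) — a
deterministic reading of "most genes, fewest unreliable edges". A Pareto
listing is available for users who prefer to inspect the trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path

from .datatypes import GeneGroupPartition, InteractionNetwork, LPParameters
from . import io as tio
from .pipeline import run_on_data
from .subnetwork import ResponseNetwork, count_low_reliability_edges


@dataclass(frozen=True)
class GridCell:
    gamma1: float
    gamma2: float
    n_src: int = 0
    n_int: int = 0
    n_snk: int = 0
    n_low_rel_edges: int = 0
    n_nodes: int = 0
    n_edges: int = 0
    outdir: str = ""
    status: str = "ok"

    @property
    def n_group_genes(self) -> int:
        return self.n_src + self.n_int + self.n_snk


def format_gamma(v: float) -> str:
    """Compact, drift-free rendering used in directory names (0.5 -> '0.5')."""
    return format(Fraction(v).limit_denominator(10**6).__float__(), "g")


def cell_dirname(g1: float, g2: float) -> str:
    return f"g1_{format_gamma(g1)}_g2_{format_gamma(g2)}"


def summarize_cell(
    rn: ResponseNetwork,
    g1: float,
    g2: float,
    low_rel_threshold: float,
    outdir: str = "",
) -> GridCell:
    types = {n.gene: n.node_type for n in rn.nodes}
    return GridCell(
        gamma1=g1,
        gamma2=g2,
        n_src=sum(1 for t in types.values() if t == "SRC"),
        n_int=sum(1 for t in types.values() if t == "INT"),
        n_snk=sum(1 for t in types.values() if t == "SNK"),
        n_low_rel_edges=count_low_reliability_edges(rn, low_rel_threshold),
        n_nodes=len(rn.nodes),
        n_edges=len(rn.edges),
        outdir=outdir,
    )


def run_grid(
    net: InteractionNetwork,
    part: GeneGroupPartition,
    gamma1_values: list[float],
    gamma2_values: list[float],
    outroot: str | Path | None = None,
    base_params: LPParameters | None = None,
    low_rel_threshold: float = 0.3,
) -> list[GridCell]:
    """Run the pipeline for every (gamma1, gamma2) combination.

    With `outroot` set, each cell writes the standard artifact files into its
    own ``g1_<v>_g2_<v>`` subdirectory (identical to a single-run invocation
    with those parameters). A failing cell is recorded with status=error and
    does not abort the grid.
    """
    base = base_params or LPParameters(gamma1=1.0, gamma2=1.0)
    cells: list[GridCell] = []
    for g1 in gamma1_values:
        for g2 in gamma2_values:
            params = replace(base, gamma1=g1, gamma2=g2)
            subdir = ""
            try:
                result = run_on_data(net, part, params)
                if outroot is not None:
                    sub = Path(outroot) / cell_dirname(g1, g2)
                    sub.mkdir(parents=True, exist_ok=True)
                    tio.write_response_network(result.response, sub, result.log)
                    tio.write_lp_artifacts(result.problem, result.solution, sub,
                                           result.log)
                    tio.write_log(result.log, sub)
                    subdir = sub.name
                cells.append(
                    summarize_cell(result.response, g1, g2,
                                   low_rel_threshold, subdir)
                )
            except Exception:
                cells.append(GridCell(gamma1=g1, gamma2=g2, status="error"))
    return cells


def select_optimal(cells: list[GridCell]) -> GridCell:
    """Deterministic lexicographic selection of the optimal grid cell.

    Maximize included input-group genes; tie-break by fewer low-reliability
    edges, then by smaller (gamma1, gamma2).
    """
    ok = [c for c in cells if c.status == "ok"]
    if not ok:
        raise ValueError("no successful grid cells to select from")
    return min(ok, key=lambda c: (-c.n_group_genes, c.n_low_rel_edges,
                                  c.gamma1, c.gamma2))


def pareto_front(cells: list[GridCell]) -> list[GridCell]:
    """Cells not dominated on (more group genes, fewer low-reliability edges)."""
    ok = [c for c in cells if c.status == "ok"]
    front = [
        c for c in ok
        if not any(
            (o.n_group_genes >= c.n_group_genes
             and o.n_low_rel_edges <= c.n_low_rel_edges
             and (o.n_group_genes > c.n_group_genes
                  or o.n_low_rel_edges < c.n_low_rel_edges))
            for o in ok
        )
    ]
    return sorted(front, key=lambda c: (c.gamma1, c.gamma2))


def write_statistics(cells: list[GridCell], outroot: str | Path) -> Path:
    """Write the per-cell statistics table (TSV, sorted by gamma pair)."""
    outroot = Path(outroot)
    outroot.mkdir(parents=True, exist_ok=True)
    lines = ["gamma1\tgamma2\tn_src\tn_int\tn_snk\tn_low_rel_edges\t"
             "n_nodes\tn_edges\tstatus"]
    for c in sorted(cells, key=lambda c: (c.gamma1, c.gamma2)):
        if c.status == "ok":
            lines.append(
                f"{format_gamma(c.gamma1)}\t{format_gamma(c.gamma2)}\t{c.n_src}\t"
                f"{c.n_int}\t{c.n_snk}\t{c.n_low_rel_edges}\t{c.n_nodes}\t"
                f"{c.n_edges}\tok"
            )
        else:
            lines.append(
                f"{format_gamma(c.gamma1)}\t{format_gamma(c.gamma2)}\t\t\t\t\t\t\t"
                f"{c.status}"
            )
    path = outroot / "statistics.txt"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def parse_gamma_range(spec_str: str) -> list[float]:
    """Parse a gamma range: comma list ('0.5,1,2') or 'start:stop:step'.

    Step grids are generated in exact Fraction arithmetic so values like 0.1
    do not drift and directory names stay clean.
    """
    spec_str = spec_str.strip()
    if ":" in spec_str:
        parts = spec_str.split(":")
        if len(parts) != 3:
            raise ValueError("range must be start:stop:step")
        start, stop, step = (Fraction(p) for p in parts)
        if step <= 0:
            raise ValueError("step must be positive")
        out = []
        v = start
        while v <= stop:
            out.append(float(v))
            v += step
        return out
    return [float(tok) for tok in spec_str.split(",") if tok.strip()]
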