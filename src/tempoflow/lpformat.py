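"""CPLEX LP text format export and a minimal re-parser.

The exporter writes the flow LP in the plain-text LP dialect understood by
every mainstream solver (objective, equality constraints, bounds). Variable
names are the canonical ``x<i>`` arc indices; the accompanying arc list file
maps them back to graph arcs. The parser reads the same dialect back into
matrix form so an exported problem can be re-solved independently of the
in-memory formulation — a round-trip check on the artifact itself.
"""

from __future__ import annotations

import re

import numpy as np
from scipy import sparse

from .model import LPProblem


def _fmt(x: float) -> str:
    return format(x, ".12g")


def export_lp(problem: LPProblem) -> str:
    """Render the problem in CPLEX LP format with canonical ordering."""
    lines: list[str] = ["Minimize", " obj:"]
    terms = []
    for name, coef in zip(problem.var_names, problem.c):
        if coef == 0:
            continue
        sign = "-" if coef < 0 else "+"
        terms.append(f" {sign} {_fmt(abs(coef))} {name}")
    if not terms:
        terms.append(f" + 0 {problem.var_names[0]}")
    lines[-1] += "".join(terms)

    lines.append("Subject To")
    a = problem.a_eq.tocsc().tocoo()
    by_row: dict[int, list[tuple[int, float]]] = {}
    for r, c_, v in zip(a.row, a.col, a.data):
        by_row.setdefault(int(r), []).append((int(c_), float(v)))
    for r, node in enumerate(problem.node_names):
        entries = sorted(by_row.get(r, []))
        if not entries:
            continue
        body = "".join(
            f" {'-' if v < 0 else '+'} {_fmt(abs(v))} {problem.var_names[c_]}"
            for c_, v in entries
        )
        lines.append(f" n{r}:{body} = 0")

    lines.append("Bounds")
    for name, (lo, hi) in zip(problem.var_names, problem.bounds):
        if hi is None:
            lines.append(f" {_fmt(lo)} <= {name} <= +inf")
        else:
            lines.append(f" {_fmt(lo)} <= {name} <= {_fmt(hi)}")
    lines.append("End")
    return "\n".join(lines) + "\n"


_TERM_RE = re.compile(r"([+-])\s*([0-9.eE+-]+)\s+(\w+)")


def _parse_terms(body: str) -> list[tuple[str, float]]:
    # normalize leading sign
    body = body.strip()
    if body and body[0] not in "+-":
        body = "+ " + body
    out = []
    for sign, coef, var in _TERM_RE.findall(body):
        out.append((var, float(coef) * (1 if sign == "+" else -1)))
    return out


def parse_lp(text: str):
    """Parse the LP dialect written by :func:`export_lp`.

    Returns ``(c, a_eq, bounds, var_names)`` with variables ordered by first
    appearance in the objective, then constraints, then bounds.
    """
    section = None
    obj_terms: list[tuple[str, float]] = []
    constraints: list[list[tuple[str, float]]] = []
    bound_map: dict[str, tuple[float, float | None]] = {}
    order: dict[str, int] = {}

    def see(var: str) -> None:
        if var not in order:
            order[var] = len(order)

    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("\\"):
            continue
        low = line.lower()
        if low in {"minimize", "maximise", "maximize", "min", "max"}:
            section = "obj"
            continue
        if low in {"subject to", "st", "s.t."}:
            section = "st"
            continue
        if low == "bounds":
            section = "bounds"
            continue
        if low == "end":
            break
        if section == "obj":
            body = line.split(":", 1)[1] if ":" in line else line
            for var, coef in _parse_terms(body):
                see(var)
                obj_terms.append((var, coef))
        elif section == "st":
            body = line.split(":", 1)[1] if ":" in line else line
            lhs, rhs = body.rsplit("=", 1)
            if float(rhs) != 0.0:
                raise ValueError("only homogeneous equality constraints supported")
            row = _parse_terms(lhs)
            for var, _ in row:
                see(var)
            constraints.append(row)
        elif section == "bounds":
            m = re.match(
                r"([0-9.eE+-]+|-?inf)\s*<=\s*(\w+)\s*<=\s*(\+?inf|[0-9.eE+-]+)", line,
                re.IGNORECASE,
            )
            if not m:
                raise ValueError(f"unsupported bound line: {line!r}")
            lo_s, var, hi_s = m.groups()
            see(var)
            lo = float(lo_s)
            hi = None if "inf" in hi_s.lower() else float(hi_s)
            bound_map[var] = (lo, hi)

    names = sorted(order, key=order.get)
    n = len(names)
    pos = {v: i for i, v in enumerate(names)}
    c = np.zeros(n)
    for var, coef in obj_terms:
        c[pos[var]] += coef
    rows, cols, vals = [], [], []
    for r, row in enumerate(constraints):
        for var, coef in row:
            rows.append(r)
            cols.append(pos[var])
            vals.append(coef)
    a_eq = sparse.csr_matrix((vals, (rows, cols)), shape=(len(constraints), n))
    bounds = [bound_map.get(v, (0.0, None)) for v in names]
    return c, a_eq, bounds, names
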