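"""Planted-path benchmark networks, perturbations and recovery scoring.

Real interactomes and time-course compendia used with this class of method
are large and externally licensed, so testing and calibration run on
synthetic analogues: a background of low-reliability edges (experimental
noise, off-pathway associations) with planted high-reliability temporal
paths early -> interior -> intermediate -> interior -> late. A configurable
fraction of interior genes is withheld from every scored group; these play
the role of transient regulators — genes that drive the response without a
measurable expression change — and should be recovered as NOD nodes.

All randomness flows through one numpy Generator seeded from the spec, so a
spec fully determines its dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    Directionality,
    GeneGroupPartition,
    Interaction,
    InteractionNetwork,
)
from .subnetwork import ResponseNetwork


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance.

    Defaults describe the reference desk-scale regime used throughout the
    package's evaluation: 300 genes, 20 planted paths with 2 interior hops,
    highly reliable planted edges (0.85-0.95) over a 2000-edge low-reliability
    background (0.1-0.3), gene scores emulating |log2 fold change| above a
    2-fold cutoff, and 30% of interior genes left unscored (transient
    regulators).
    """

    n_genes: int = 300
    n_paths: int = 20
    path_len: int = 2  # interior genes per path (excluding the transit gene)
    planted_weight_dist: tuple[float, float] = (0.85, 0.95)
    background_edges: int = 2000
    background_weight_dist: tuple[float, float] = (0.1, 0.3)
    score_dist: tuple[float, float] = (1.0, 3.0)
    frac_unscored_interior: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_unscored_interior <= 1):
            raise ValueError("frac_unscored_interior must be in [0, 1]")
        if self.planted_weight_dist[0] <= self.background_weight_dist[1]:
            raise ValueError("planted weight range must lie above background range")
        if self.genes_per_path * self.n_paths > self.n_genes:
            raise ValueError("paths need more genes than n_genes provides")

    @property
    def genes_per_path(self) -> int:
        return self.path_len + 3  # early + interiors (incl. transit) + late

    def to_config(self) -> str:
        pairs = [
            ("n_genes", self.n_genes),
            ("n_paths", self.n_paths),
            ("path_len", self.path_len),
            ("planted_weight_low", self.planted_weight_dist[0]),
            ("planted_weight_high", self.planted_weight_dist[1]),
            ("background_edges", self.background_edges),
            ("background_weight_low", self.background_weight_dist[0]),
            ("background_weight_high", self.background_weight_dist[1]),
            ("score_low", self.score_dist[0]),
            ("score_high", self.score_dist[1]),
            ("frac_unscored_interior", self.frac_unscored_interior),
            ("seed", self.seed),
        ]
        return "\n".join(f"{k}={v}" for k, v in pairs) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "SyntheticSpec":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
        return cls(
            n_genes=int(kv["n_genes"]),
            n_paths=int(kv["n_paths"]),
            path_len=int(kv["path_len"]),
            planted_weight_dist=(float(kv["planted_weight_low"]),
                                 float(kv["planted_weight_high"])),
            background_edges=int(kv["background_edges"]),
            background_weight_dist=(float(kv["background_weight_low"]),
                                    float(kv["background_weight_high"])),
            score_dist=(float(kv["score_low"]), float(kv["score_high"])),
            frac_unscored_interior=float(kv["frac_unscored_interior"]),
            seed=int(kv["seed"]),
        )


@dataclass
class GroundTruth:
    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    planted_transit_genes: set[str] = field(default_factory=set)
    planted_interior_unscored: set[str] = field(default_factory=set)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_planted_network(
    spec: SyntheticSpec,
) -> tuple[InteractionNetwork, GeneGroupPartition, GroundTruth]:
    """Generate one benchmark instance deterministically from its spec.

    Each planted path uses distinct genes: an early-group start, `path_len`
    interior genes split around a designated intermediate-group transit gene,
    and a late-group end, joined by directed high-weight edges. Scored
    interior genes join the intermediate group (joining the early or late
    group would hand them terminal arcs and let flow bypass planted edges
    structurally). Background edges are bidirectional low-weight pairs drawn
    uniformly over the whole gene universe.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [_gene_name(i) for i in range(spec.n_genes)]

    net = InteractionNetwork()
    truth = GroundTruth()
    early: dict[str, float] = {}
    intermediate: dict[str, float] = {}
    late: dict[str, float] = {}

    def score() -> float:
        return float(rng.uniform(*spec.score_dist))

    # reserve distinct genes for the planted paths
    n_reserved = spec.genes_per_path * spec.n_paths
    reserved = rng.choice(spec.n_genes, size=n_reserved, replace=False)
    cursor = 0
    interior_pool: list[str] = []
    for _ in range(spec.n_paths):
        block = [genes[i] for i in reserved[cursor:cursor + spec.genes_per_path]]
        cursor += spec.genes_per_path
        start, end = block[0], block[-1]
        inner = block[1:-1]  # path_len interiors + transit gene
        transit_pos = spec.path_len // 2  # transit sits mid-path
        transit = inner[transit_pos]
        path = [start] + inner + [end]
        for u, v in zip(path, path[1:]):
            w = float(rng.uniform(*spec.planted_weight_dist))
            net.add(Interaction(u, v, Directionality.UNIDIRECTIONAL, w))
            truth.planted_edges.add((u, v))
        early[start] = score()
        late[end] = score()
        intermediate[transit] = score()
        truth.planted_transit_genes.add(transit)
        interior_pool.extend(g for g in inner if g != transit)

    # withhold a fraction of interior genes from all groups (transient regulators)
    n_unscored = int(round(spec.frac_unscored_interior * len(interior_pool)))
    if interior_pool and n_unscored:
        picks = rng.choice(len(interior_pool), size=n_unscored, replace=False)
        unscored = {interior_pool[i] for i in picks}
    else:
        unscored = set()
    truth.planted_interior_unscored = unscored
    for g in interior_pool:
        if g not in unscored:
            intermediate[g] = score()

    # background: bidirectional low-weight edges between random distinct pairs
    added = 0
    attempts = 0
    existing = net.ordered_pairs
    while added < spec.background_edges:
        attempts += 1
        if attempts > 10_000 * max(spec.background_edges, 1):
            raise ValueError("cannot place background edges: network too dense")
        i, j = rng.integers(0, spec.n_genes, size=2)
        if i == j:
            continue
        u, v = genes[int(i)], genes[int(j)]
        if (u, v) in existing or (v, u) in existing:
            continue
        w = float(rng.uniform(*spec.background_weight_dist))
        net.add(Interaction(u, v, Directionality.BIDIRECTIONAL, w))
        net.add(Interaction(v, u, Directionality.BIDIRECTIONAL, w))
        existing.add((u, v))
        existing.add((v, u))
        added += 1

    # n_paths=0 yields a pure background network with empty groups and an
    # empty ground truth; downstream validation rejects empty groups, which
    # is the correct behaviour for such a null instance.
    part = GeneGroupPartition(early=early, intermediate=intermediate, late=late)
    return net, part, truth


def perturb_add_edges(
    net: InteractionNetwork,
    n: int,
    seed: int,
    weight_dist: tuple[float, float] = (0.1, 0.3),
) -> InteractionNetwork:
    """Add `n` random bidirectional background-weight edges between existing genes.

    New edges never duplicate an existing ordered pair (in either
    orientation); sampling is deterministic per seed.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    genes = sorted(net.genes)
    m = len(genes)
    existing = net.ordered_pairs
    out = net.copy()
    added = 0
    attempts = 0
    limit = 10_000 * max(n, 1)
    while added < n:
        attempts += 1
        if attempts > limit:
            raise ValueError(f"cannot place {n} new edges (network too dense)")
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        u, v = genes[int(i)], genes[int(j)]
        if (u, v) in existing or (v, u) in existing:
            continue
        w = float(rng.uniform(*weight_dist))
        out.add(Interaction(u, v, Directionality.BIDIRECTIONAL, w))
        out.add(Interaction(v, u, Directionality.BIDIRECTIONAL, w))
        existing.add((u, v))
        existing.add((v, u))
        added += 1
    return out


def perturb_remove_edges(
    net: InteractionNetwork,
    n: int,
    seed: int,
    exclude: set[tuple[str, str]] | None = None,
) -> InteractionNetwork:
    """Remove `n` uniformly sampled interactions (a bidirectional pair counts
    as one interaction). Pairs listed in `exclude` are protected — used by the
    robustness experiments to confine removal to background edges.
    """
    rng = np.random.default_rng(seed)
    exclude = exclude or set()
    records = [
        inter for inter in net.undirected_interactions()
        if (inter.source, inter.target) not in exclude
        and (inter.target, inter.source) not in exclude
    ]
    if not (0 <= n <= len(records)):
        raise ValueError(f"cannot remove {n} of {len(records)} removable edges")
    records.sort(key=lambda r: (r.source, r.target))
    picks = set(rng.choice(len(records), size=n, replace=False).tolist()) if n else set()
    removed_pairs: set[tuple[str, str]] = set()
    for k in picks:
        r = records[k]
        removed_pairs.add((r.source, r.target))
        if r.directionality is Directionality.BIDIRECTIONAL:
            removed_pairs.add((r.target, r.source))
    kept = {
        (i.source, i.target): i
        for i in net
        if (i.source, i.target) not in removed_pairs
    }
    return InteractionNetwork(kept)


@dataclass(frozen=True)
class RecoveryMetrics:
    edge_precision: float
    edge_recall: float
    transit_recall: float
    nod_recall: float


def evaluate_recovery(rn: ResponseNetwork, truth: GroundTruth) -> RecoveryMetrics:
    """Score a predicted network against the planted ground truth."""
    if not truth.planted_edges:
        raise ValueError("empty ground truth: recovery metrics undefined")
    predicted = rn.edge_pairs
    hit = predicted & truth.planted_edges
    edge_recall = len(hit) / len(truth.planted_edges)
    edge_precision = len(hit) / len(predicted) if predicted else 0.0

    if truth.planted_transit_genes:
        types = {n.gene: n.node_type for n in rn.nodes}
        t_hit = sum(
            1 for g in truth.planted_transit_genes if types.get(g) == "INT"
        )
        transit_recall = t_hit / len(truth.planted_transit_genes)
    else:
        transit_recall = float("nan")

    if truth.planted_interior_unscored:
        types = {n.gene: n.node_type for n in rn.nodes}
        n_hit = sum(
            1 for g in truth.planted_interior_unscored if types.get(g) == "NOD"
        )
        nod_recall = n_hit / len(truth.planted_interior_unscored)
    else:
        nod_recall = float("nan")
    return RecoveryMetrics(edge_precision=edge_precision, edge_recall=edge_recall,
                           transit_recall=transit_recall, nod_recall=nod_recall)


def recovered_planted_edges(
    rn: ResponseNetwork, truth: GroundTruth
) -> set[tuple[str, str]]:
    return rn.edge_pairs & truth.planted_edges


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def max_consecutive_overlap(
    rn: ResponseNetwork, reference_edges: set[tuple[str, str]]
) -> int:
    """Length (edges) of the longest directed path common to `rn` and a
    reference pathway's edge set.

    Exhaustive DFS over the (small) intersection graph; nodes are not
    revisited within a path, so cycles in the intersection are handled.
    """
    common = rn.edge_pairs & set(reference_edges)
    if not common:
        return 0
    succ: dict[str, list[str]] = {}
    for u, v in sorted(common):
        succ.setdefault(u, []).append(v)

    best = 0

    def dfs(node: str, length: int, visited: set[str]) -> None:
        nonlocal best
        best = max(best, length)
        for nxt in succ.get(node, []):
            if nxt not in visited:
                visited.add(nxt)
                dfs(nxt, length + 1, visited)
                visited.remove(nxt)

    for start in {u for u, _ in common}:
        dfs(start, 0, {start})
    return best
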