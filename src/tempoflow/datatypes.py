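"""Core domain types shared across the package.

The vocabulary follows the field's convention for flow-based response-network
inference: three mutually exclusive temporal gene groups (initial response
genes, intermediate regulators, late effectors), each gene scored by the
magnitude of its expression change, routed through a molecular interaction
network whose edges carry reliability weights in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator


class Directionality(str, Enum):
    """Orientation of a molecular interaction as given in the input network."""

    UNIDIRECTIONAL = "u"
    BIDIRECTIONAL = "b"


#: Tokens accepted in the network file's directionality column (case-insensitive).
DIRECTIONALITY_TOKENS = {
    "u": Directionality.UNIDIRECTIONAL,
    "unidirectional": Directionality.UNIDIRECTIONAL,
    "d": Directionality.UNIDIRECTIONAL,
    "directed": Directionality.UNIDIRECTIONAL,
    "b": Directionality.BIDIRECTIONAL,
    "bidirectional": Directionality.BIDIRECTIONAL,
    "pp": Directionality.BIDIRECTIONAL,
}


@dataclass(frozen=True)
class ScoredGene:
    """A gene with a positive expression-change score (typically |log FC|)."""

    name: str
    score: float

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene name must be non-empty")
        if not self.score > 0:
            raise ValueError(f"gene score must be positive, got {self.score!r}")


@dataclass(frozen=True)
class Interaction:
    """One ordered interaction arc with its reliability weight.

    Bidirectional input edges are expanded to two ordered interactions at read
    time; ``directionality`` records the origin for output reporting.
    """

    source: str
    target: str
    directionality: Directionality
    weight: float

    def __post_init__(self) -> None:
        if not (0 < self.weight <= 1):
            raise ValueError(f"reliability weight must be in (0, 1], got {self.weight!r}")
        if self.source == self.target:
            raise ValueError("self-loops are not allowed")


class InteractionNetwork:
    """Deduplicated weighted interaction graph over ordered gene pairs.

    Stores one :class:`Interaction` per ordered (source, target) pair; duplicate
    pairs keep the maximum weight, which makes construction order-independent.
    """

    def __init__(self, interactions: dict[tuple[str, str], Interaction] | None = None):
        self._arcs: dict[tuple[str, str], Interaction] = dict(interactions or {})

    def add(self, inter: Interaction) -> bool:
        """Insert an ordered interaction, keeping the max weight on duplicates.

        Returns True if the interaction was new or replaced a lower-weight
        duplicate, False if an equal-or-better duplicate already existed.
        """
        key = (inter.source, inter.target)
        old = self._arcs.get(key)
        if old is None or inter.weight > old.weight:
            self._arcs[key] = inter
            return old is None
        return False

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._arcs

    def __len__(self) -> int:
        return len(self._arcs)

    def __iter__(self) -> Iterator[Interaction]:
        return iter(self._arcs.values())

    def get(self, source: str, target: str) -> Interaction | None:
        return self._arcs.get((source, target))

    @property
    def ordered_pairs(self) -> set[tuple[str, str]]:
        return set(self._arcs)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for s, t in self._arcs:
            out.add(s)
            out.add(t)
        return out

    def gene_index(self) -> dict[str, int]:
        """Stable integer ids for genes (sorted lexicographically)."""
        return {g: i for i, g in enumerate(sorted(self.genes))}

    def undirected_interactions(self) -> list[Interaction]:
        """Collapse the two arcs of a bidirectional pair into one record.

        Used when writing a network back to the 4-column input format.
        """
        seen: set[tuple[str, str]] = set()
        out: list[Interaction] = []
        for (s, t), inter in sorted(self._arcs.items()):
            if inter.directionality is Directionality.BIDIRECTIONAL:
                if (t, s) in seen:
                    continue
                seen.add((s, t))
            out.append(inter)
        return out

    def copy(self) -> "InteractionNetwork":
        return InteractionNetwork(dict(self._arcs))


@dataclass(frozen=True)
class GeneGroupPartition:
    """The three mutually exclusive temporal gene groups, name -> score."""

    early: dict[str, float]
    intermediate: dict[str, float]
    late: dict[str, float]

    def __post_init__(self) -> None:
        e, i, l = set(self.early), set(self.intermediate), set(self.late)
        overlap = (e & i) | (e & l) | (i & l)
        if overlap:
            raise ValueError(
                "gene groups must be mutually exclusive; offenders: "
                + ", ".join(sorted(overlap))
            )

    @property
    def all_genes(self) -> set[str]:
        return set(self.early) | set(self.intermediate) | set(self.late)

    def group_of(self, gene: str) -> str | None:
        if gene in self.early:
            return "early"
        if gene in self.intermediate:
            return "intermediate"
        if gene in self.late:
            return "late"
        return None


class LogCategory(str, Enum):
    DUPLICATE_EDGE = "duplicate_edge"
    DUPLICATE_GENE = "duplicate_gene"
    BAD_EDGE_SCORE = "bad_edge_score"
    BAD_GENE_SCORE = "bad_gene_score"
    SELF_LOOP = "self_loop"
    GENE_NOT_IN_NETWORK = "gene_not_in_network"
    GROUP_OVERLAP = "group_overlap"
    BAD_DIRECTIONALITY = "bad_directionality"
    MALFORMED_LINE = "malformed_line"
    INFO = "info"
    WARNING = "warning"


@dataclass
class ValidationLog:
    """Ordered record of every input line skipped or transformed while reading."""

    events: list[tuple[LogCategory, str]] = field(default_factory=list)

    def record(self, category: LogCategory, detail: str) -> None:
        self.events.append((category, detail))

    def count(self, category: LogCategory) -> int:
        return sum(1 for c, _ in self.events if c is category)

    def skip_count(self) -> int:
        """Number of events that correspond to a discarded/modified input line."""
        informational = {LogCategory.INFO, LogCategory.WARNING}
        return sum(1 for c, _ in self.events if c not in informational)

    def extend(self, other: "ValidationLog") -> None:
        self.events.extend(other.events)

    def lines(self) -> list[str]:
        return [f"{c.value}\t{d}" for c, d in self.events]


class InputError(ValueError):
    """Fatal problem with the user-supplied inputs."""


@dataclass(frozen=True)
class LPParameters:
    """Tunable parameters of the flow model.

    gamma1 rewards each unit of flow leaving the artificial source through an
    initial-response gene; gamma2 rewards each unit of flow crossing an
    intermediate regulator's transit arc. Larger values pull more members of
    the respective group into the predicted network.
    """

    gamma1: float
    gamma2: float
    interaction_capacity: float = 1.0
    flow_tolerance: float = 1e-6
    weight_floor: float = 1e-6

    def __post_init__(self) -> None:
        # The user-facing contract requires strictly positive gammas (enforced
        # at the CLI); zero is tolerated here because the degenerate no-reward
        # model (all-zero optimal flow) is well defined and useful in tests.
        if self.gamma1 < 0:
            raise ValueError("gamma1 must be non-negative")
        if self.gamma2 < 0:
            raise ValueError("gamma2 must be non-negative")
        if not self.interaction_capacity > 0:
            raise ValueError("interaction_capacity must be positive")
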