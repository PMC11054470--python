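"""Core domain types for the hand-eczema drug-repurposing network pipeline.

Gene identity throughout the package is the bare HGNC-style symbol string,
case-normalized to upper case; no alias resolution is attempted. The reference
interactome and the assembled disease network are undirected simple graphs over
such symbols, backed by :class:`networkx.Graph`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_symbol",
    "Direction",
    "SeedOrigin",
    "NodeRole",
    "EffectKind",
    "EffectDirection",
    "PriceBand",
    "PracticalIssue",
    "DEGRecord",
    "SeedGene",
    "Interactome",
    "GeneNetwork",
    "AnnotationCollection",
    "DrugEffectRow",
    "DrugEffectTable",
    "SNPAssociationTable",
    "DrugAnnotation",
    "ScoreBreakdown",
]


def normalize_symbol(raw: object) -> str:
    """Case-normalize a gene symbol.

    Symbols are compared case-insensitively by storing the upper-cased token;
    whitespace inside a symbol is invalid.
    """
    token = str(raw).strip()
    if not token:
        raise ValueError("empty gene symbol")
    if any(c.isspace() for c in token):
        raise ValueError(f"gene symbol contains whitespace: {raw!r}")
    return token.upper()


class Direction(str, Enum):
    """Differential-expression direction of a DEG in lesional vs healthy skin."""

    UP = "up"
    DOWN = "down"

    @classmethod
    def parse(cls, token: str) -> "Direction":
        t = str(token).strip().lower()
        if t in ("up", "upregulated", "up-regulated", "increased"):
            return cls.UP
        if t in ("down", "downregulated", "down-regulated", "decreased"):
            return cls.DOWN
        raise ValueError(f"unknown DEG direction: {token!r}")

    @property
    def opposite(self) -> "Direction":
        return Direction.DOWN if self is Direction.UP else Direction.UP


class SeedOrigin(str, Enum):
    """Where a seed gene came from: transcriptomics (DEG) or genomics (QTL)."""

    DEG = "DEG"
    QTL = "QTL"


class NodeRole(str, Enum):
    DEG = "DEG"
    QTL = "QTL"
    LINKER = "LINKER"


class EffectKind(str, Enum):
    """Drug–gene relation kind: physical target vs transcriptomic effect."""

    TARGET = "target"
    EXPRESSION_EFFECT = "expression_effect"

    @classmethod
    def parse(cls, token: str) -> "EffectKind":
        t = str(token).strip().lower()
        if t in ("target", "physical", "physical_target"):
            return cls.TARGET
        if t in ("expression_effect", "expression", "transcriptomic"):
            return cls.EXPRESSION_EFFECT
        raise ValueError(f"unknown drug-gene effect kind: {token!r}")


#: Free-text vocabulary mapped onto the normalized expression-effect directions.
#: DrugBank-style sources phrase the same effect many ways.
_EFFECT_SYNONYMS = {
    "increase": "increase",
    "increases": "increase",
    "increased": "increase",
    "up": "increase",
    "up-regulates": "increase",
    "upregulates": "increase",
    "up-regulate": "increase",
    "induces expression": "increase",
    "decrease": "decrease",
    "decreases": "decrease",
    "decreased": "decrease",
    "down": "decrease",
    "down-regulates": "decrease",
    "downregulates": "decrease",
    "down-regulate": "decrease",
    "represses expression": "decrease",
    "unknown": "unknown",
    "unclear": "unknown",
    "na": "unknown",
    "n/a": "unknown",
    "": "unknown",
}


class EffectDirection(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, token: str) -> "EffectDirection":
        t = str(token).strip().lower()
        try:
            return cls(_EFFECT_SYNONYMS[t])
        except KeyError:
            raise ValueError(f"unknown effect direction: {token!r}") from None


class PriceBand(str, Enum):
    """Annual-cost band of a drug (EUR/year), as used by the ranking rubric."""

    VERY_LOW = "very_low"  # < 50 EUR/year
    LOW = "low"  # 50-500 EUR/year
    MID = "mid"  # neutral band
    VERY_HIGH = "very_high"  # > 20000 EUR/year
    UNAVAILABLE = "unavailable"  # price not retrievable


class PracticalIssue(str, Enum):
    NONE = "none"
    ISSUE = "issue"  # e.g. parenteral-only administration
    SEVERE = "severe"  # e.g. gas or skin-substitute formulation


@dataclass(frozen=True)
class DEGRecord:
    """A differentially expressed gene with its disease direction."""

    gene: str
    direction: Direction

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction.parse(self.direction))


@dataclass(frozen=True)
class SeedGene:
    """A network seed gene with its origin layer (DEG or QTL)."""

    gene: str
    origin: SeedOrigin

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        if not isinstance(self.origin, SeedOrigin):
            object.__setattr__(self, "origin", SeedOrigin(self.origin))


class Interactome:
    """Reference universe of undirected gene–gene functional interactions.

    Self-loops are dropped (with a logged count) and unordered duplicates are
    collapsed; an optional interaction-type label per edge is preserved for
    display only and plays no role in topology.
    """

    def __init__(self, edges: Iterable[Sequence[str]]):
        g = nx.Graph()
        n_self_loops = 0
        for row in edges:
            if len(row) < 2:
                raise ValueError(f"edge row needs >= 2 entries, got {row!r}")
            a = normalize_symbol(row[0])
            b = normalize_symbol(row[1])
            label = str(row[2]) if len(row) > 2 and row[2] is not None else None
            if a == b:
                n_self_loops += 1
                continue
            if not g.has_edge(a, b):
                g.add_edge(a, b, label=label)
        if n_self_loops:
            logger.info("dropped %d self-loop edge(s)", n_self_loops)
        self._g = g
        self.n_self_loops_dropped = n_self_loops

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> frozenset:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset:
        return frozenset(frozenset(e) for e in self._g.edges)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self._g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"Interactome(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


class GeneNetwork:
    """The assembled disease network: role-typed nodes over induced edges.

    Nodes carry a role (DEG, QTL or LINKER). Seed genes without any
    interactome interaction are retained as degree-0 nodes; linker genes, by
    construction, must be connected.
    """

    def __init__(self, graph: nx.Graph, roles: Mapping[str, NodeRole]):
        roles = {normalize_symbol(g): NodeRole(r) for g, r in roles.items()}
        for u, v in graph.edges:
            if u not in roles or v not in roles:
                raise ValueError(f"edge endpoint without role: {u}-{v}")
        for g in graph.nodes:
            if g not in roles:
                raise ValueError(f"node without role: {g}")
        for g, role in roles.items():
            if g not in graph:
                raise ValueError(f"role assigned to absent node: {g}")
            if role is NodeRole.LINKER and graph.degree(g) == 0:
                raise ValueError(f"linker {g} has degree 0")
        self.graph = graph
        self.roles = roles

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def isolated_seeds(self) -> list:
        return sorted(
            g
            for g, role in self.roles.items()
            if role is not NodeRole.LINKER and self.graph.degree(g) == 0
        )

    def genes_with_role(self, role: NodeRole) -> frozenset:
        return frozenset(g for g, r in self.roles.items() if r is role)

    @property
    def seed_genes(self) -> frozenset:
        return self.genes_with_role(NodeRole.DEG) | self.genes_with_role(NodeRole.QTL)

    def to_dict(self) -> dict:
        return {
            "nodes": {g: self.roles[g].value for g in sorted(self.graph.nodes)},
            "edges": sorted(sorted(e) for e in self.graph.edges),
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GeneNetwork":
        g = nx.Graph()
        g.add_nodes_from(payload["nodes"])
        g.add_edges_from(payload["edges"])
        return cls(g, {k: NodeRole(v) for k, v in payload["nodes"].items()})

    def __repr__(self) -> str:
        return (
            f"GeneNetwork(n_nodes={self.graph.number_of_nodes()}, "
            f"n_edges={self.graph.number_of_edges()})"
        )


@dataclass
class AnnotationCollection:
    """A named gene-set collection (GMT-style) under one functional category."""

    category: str
    sets: dict  # set_name -> frozenset of gene symbols

    def __post_init__(self) -> None:
        clean = {}
        for name, members in self.sets.items():
            members = frozenset(normalize_symbol(m) for m in members)
            if not members:
                raise ValueError(f"empty gene set: {name!r}")
            if name in clean:
                raise ValueError(f"duplicate set name: {name!r}")
            clean[str(name)] = members
        self.sets = clean

    @property
    def all_genes(self) -> frozenset:
        out: frozenset = frozenset()
        for members in self.sets.values():
            out |= members
        return out


@dataclass(frozen=True)
class DrugEffectRow:
    drug: str
    gene: str
    kind: EffectKind
    direction: EffectDirection

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene", normalize_symbol(self.gene))
        object.__setattr__(self, "drug", str(self.drug).strip())
        if not self.drug:
            raise ValueError("empty drug label")
        if not isinstance(self.kind, EffectKind):
            object.__setattr__(self, "kind", EffectKind.parse(self.kind))
        if not isinstance(self.direction, EffectDirection):
            object.__setattr__(self, "direction", EffectDirection.parse(self.direction))


class DrugEffectTable:
    """Drug→gene rows: physical targets and transcriptomic expression effects.

    (drug, gene, kind) is unique. Exact duplicate rows collapse silently;
    rows agreeing on the key but conflicting on direction collapse to
    direction UNKNOWN with a logged count (the conflict means the reported
    direction cannot be trusted, and the ranking rubric penalizes unclear
    directions downstream rather than guessing).
    """

    def __init__(self, rows: Iterable[DrugEffectRow]):
        table: dict = {}
        n_conflicts = 0
        for row in rows:
            if not isinstance(row, DrugEffectRow):
                row = DrugEffectRow(*row)
            key = (row.drug, row.gene, row.kind)
            if key in table and table[key] != row.direction:
                if table[key] is not EffectDirection.UNKNOWN:
                    n_conflicts += 1
                table[key] = EffectDirection.UNKNOWN
            else:
                table[key] = row.direction
        if n_conflicts:
            logger.info(
                "collapsed %d conflicting drug-gene direction(s) to unknown",
                n_conflicts,
            )
        self._table = table
        self.n_conflicts = n_conflicts

    @property
    def rows(self) -> list:
        return [
            DrugEffectRow(drug, gene, kind, direction)
            for (drug, gene, kind), direction in sorted(
                self._table.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
            )
        ]

    def of_kind(self, kind: EffectKind) -> list:
        return [r for r in self.rows if r.kind is kind]

    @property
    def drugs(self) -> frozenset:
        return frozenset(drug for drug, _, _ in self._table)

    def __len__(self) -> int:
        return len(self._table)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DrugEffectTable):
            return NotImplemented
        return self._table == other._table


class SNPAssociationTable:
    """GWAS variant associations: (variant id, p-value in (0, 1])."""

    def __init__(self, rows: Iterable[Sequence]):
        clean = []
        for variant, p in rows:
            p = float(p)
            if not (0.0 < p <= 1.0) or math.isnan(p):
                raise ValueError(f"p-value out of (0,1] for {variant}: {p}")
            clean.append((str(variant), p))
        self.rows = clean

    def genome_wide_significant(self, threshold: float = 5e-8) -> list:
        """Variants with p strictly below the genome-wide threshold."""
        return [v for v, p in self.rows if p < threshold]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class DrugAnnotation:
    """Per-drug ranking-rubric inputs, curated from the literature.

    Every field is mandatory: the rubric is undefined on partial records.
    """

    drug: str
    immunomod_general: bool
    immunomod_skin: bool
    n_network_targets: int
    topical_possible: bool
    who_essential: bool
    price_band: PriceBand
    has_atc: bool
    orderable: bool
    direction_clear: bool
    grade3to5_risk: bool
    practical_issue: PracticalIssue

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) is None:
                raise ValueError(f"missing annotation field: {name}")
        if not isinstance(self.price_band, PriceBand):
            self.price_band = PriceBand(self.price_band)
        if not isinstance(self.practical_issue, PracticalIssue):
            self.practical_issue = PracticalIssue(self.practical_issue)
        self.n_network_targets = int(self.n_network_targets)
        if self.n_network_targets < 0:
            raise ValueError("n_network_targets must be non-negative")

    @classmethod
    def neutral(cls, drug: str, **overrides) -> "DrugAnnotation":
        """An all-neutral annotation (no bonuses, no penalties) to build from."""
        base = dict(
            drug=drug,
            immunomod_general=False,
            immunomod_skin=False,
            n_network_targets=0,
            topical_possible=False,
            who_essential=False,
            price_band=PriceBand.MID,
            has_atc=True,
            orderable=True,
            direction_clear=True,
            grade3to5_risk=False,
            practical_issue=PracticalIssue.NONE,
        )
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class ScoreBreakdown:
    """Audited rubric output: per-criterion applied points and their total."""

    drug: str
    applied: tuple  # ((criterion_id, points), ...)
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(p for _, p in self.applied):
            raise ValueError(
                f"total {self.total} != sum of applied points for {self.drug}"
            )
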