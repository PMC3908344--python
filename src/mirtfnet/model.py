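"""Domain types shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

COHORTS = ("NSCLC", "SCLC")
NETWORK_COHORTS = ("NSCLC", "SCLC", "common")
DIRECTIONS = ("up", "down")
#: direction assigned when one cohort reports "up" and another report says
#: "down" for the same miRNA *within the same cohort*
CONFLICT = "conflict"
#: derived label for a miRNA carrying opposite directions in the two cohorts
DIFFERENTIAL = "differential"

GO_CATEGORIES = (
    "transcription",
    "cell_cycle",
    "cell_organization_biogenesis",
    "other",
)

NODE_GENE = "gene"
NODE_MIRNA = "mirna"
EDGE_PPI = "ppi"
EDGE_TARGETS = "targets"
EDGE_REGULATES = "regulates"
EDGE_TYPES = (EDGE_PPI, EDGE_TARGETS, EDGE_REGULATES)

GROUP_NAMES = (
    "unique_SCLC",
    "common_SCLC_NSCLC",
    "common_all",
    "common_NSCLC_general",
    "NSCLC_specific",
    "general_specific",
)

STRATEGY_NAMES = ("key_node", "shortest_path", "enrichment_rank")


class FormatError(ValueError):
    """A malformed input file (bad header, bad token, bad line)."""


class ConfigError(ValueError):
    """An invalid or infeasible configuration value."""


@dataclass(frozen=True)
class MiRNAAssociation:
    """One miRNA's cohort memberships with per-cohort regulation direction."""

    mirna_id: str
    directions: Mapping[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.directions:
            raise ValueError(
                f"miRNA {self.mirna_id!r}: at least one cohort is required"
            )
        for cohort, direction in self.directions.items():
            if cohort not in COHORTS:
                raise ValueError(
                    f"miRNA {self.mirna_id!r}: unknown cohort {cohort!r}"
                )
            if direction not in DIRECTIONS + (CONFLICT, DIFFERENTIAL):
                raise ValueError(
                    f"miRNA {self.mirna_id!r}: unknown direction {direction!r}"
                )

    def __hash__(self) -> int:  # directions is a dict; hash a frozen view
        return hash(
            (self.mirna_id, tuple(sorted(self.directions.items())), self.source)
        )

    @property
    def subtypes(self) -> frozenset[str]:
        return frozenset(self.directions)

    def is_differential(self) -> bool:
        """True when the two cohorts report opposite directions."""
        if len(self.directions) < 2:
            return False
        if DIFFERENTIAL in self.directions.values():
            return True
        plain = {d for d in self.directions.values() if d in DIRECTIONS}
        return len(plain) == 2


@dataclass(frozen=True)
class TargetEdge:
    """A validated miRNA -> target-gene relationship."""

    mirna_id: str
    gene_id: str
    validated: bool = True


@dataclass(frozen=True)
class GeneAnnotation:
    """A flat gene -> GO-term assignment with a coarse category label."""

    gene_id: str
    go_term: str
    go_category: str = "other"

    def __post_init__(self) -> None:
        if self.go_category not in GO_CATEGORIES:
            raise ValueError(f"unknown go_category {self.go_category!r}")


@dataclass(frozen=True)
class RegulationEdge:
    """A TF -> miRNA transcriptional regulation relationship."""

    tf_id: str
    mirna_id: str
    mode: str = "unknown"

    def __post_init__(self) -> None:
        if self.mode not in ("activates", "represses", "unknown"):
            raise ValueError(f"unknown regulation mode {self.mode!r}")


class RegulatoryNetwork:
    """A typed graph over gene and miRNA nodes.

    ``ppi`` edges are undirected and stored canonically with the
    lexicographically smaller endpoint first; ``targets`` (miRNA -> gene) and
    ``regulates`` (gene -> miRNA) edges are directed.
    """

    def __init__(self, cohort: str = "common") -> None:
        if cohort not in NETWORK_COHORTS:
            raise ValueError(f"unknown cohort {cohort!r}")
        self.cohort = cohort
        self._nodes: dict[str, str] = {}
        self._edges: set[tuple[str, str, str]] = set()

    # -- construction -------------------------------------------------

    def add_node(self, node_id: str, node_type: str = NODE_GENE) -> None:
        if node_type not in (NODE_GENE, NODE_MIRNA):
            raise ValueError(f"unknown node type {node_type!r}")
        existing = self._nodes.get(node_id)
        if existing is not None and existing != node_type:
            raise ValueError(
                f"node {node_id!r} already registered as {existing!r}"
            )
        self._nodes[node_id] = node_type

    def add_edge(self, source: str, target: str, edge_type: str) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {edge_type!r}")
        for endpoint in (source, target):
            if endpoint not in self._nodes:
                raise ValueError(f"edge endpoint {endpoint!r} is not a node")
        if edge_type == EDGE_PPI:
            source, target = min(source, target), max(source, target)
        self._edges.add((source, target, edge_type))

    def remove_node(self, node_id: str) -> None:
        del self._nodes[node_id]
        self._edges = {
            e for e in self._edges if node_id not in (e[0], e[1])
        }

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> dict[str, str]:
        return dict(self._nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str, str]]:
        return frozenset(self._edges)

    def node_type(self, node_id: str) -> str:
        return self._nodes[node_id]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._nodes

    def has_edge(self, source: str, target: str, edge_type: str) -> bool:
        if edge_type == EDGE_PPI:
            source, target = min(source, target), max(source, target)
        return (source, target, edge_type) in self._edges

    def gene_nodes(self) -> frozenset[str]:
        return frozenset(
            n for n, t in self._nodes.items() if t == NODE_GENE
        )

    def mirna_nodes(self) -> frozenset[str]:
        return frozenset(
            n for n, t in self._nodes.items() if t == NODE_MIRNA
        )

    def n_nodes(self) -> int:
        return len(self._nodes)

    def n_edges(self) -> int:
        return len(self._edges)

    def degree(self, node_id: str) -> int:
        """Total degree across all edge types (ppi edges count once)."""
        if node_id not in self._nodes:
            raise KeyError(node_id)
        return sum(
            1 for s, t, _ in self._edges if node_id in (s, t)
        )

    def copy(self, cohort: str | None = None) -> "RegulatoryNetwork":
        out = RegulatoryNetwork(cohort or self.cohort)
        out._nodes = dict(self._nodes)
        out._edges = set(self._edges)
        return out

    def to_undirected(self) -> nx.Graph:
        """Collapse edge types into a simple undirected graph."""
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from((s, t) for s, t, _ in self._edges)
        return g

    # -- dunder -------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            self.cohort == other.cohort
            and self._nodes == other._nodes
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        return (
            f"RegulatoryNetwork(cohort={self.cohort!r}, "
            f"nodes={len(self._nodes)}, edges={len(self._edges)})"
        )

    @classmethod
    def from_parts(
        cls,
        cohort: str,
        genes: Iterable[str] = (),
        mirnas: Iterable[str] = (),
        edges: Iterable[tuple[str, str, str]] = (),
    ) -> "RegulatoryNetwork":
        net = cls(cohort)
        for g in genes:
            net.add_node(g, NODE_GENE)
        for m in mirnas:
            net.add_node(m, NODE_MIRNA)
        for s, t, k in edges:
            net.add_edge(s, t, k)
        return net


@dataclass(frozen=True)
class GeneGroupClassification:
    """Six-way gene classification produced by cohort-network subtraction.

    Groups 1-3 (``unique_SCLC``, ``common_SCLC_NSCLC``, ``common_all``)
    coincide whenever the SCLC gene set is contained in both the NSCLC and
    the common network.
    """

    unique_SCLC: frozenset[str]
    common_SCLC_NSCLC: frozenset[str]
    common_all: frozenset[str]
    common_NSCLC_general: frozenset[str]
    NSCLC_specific: frozenset[str]
    general_specific: frozenset[str]

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {name: getattr(self, name) for name in GROUP_NAMES}

    def group_of(self, gene_id: str) -> str | None:
        """Most specific group containing ``gene_id`` (groups 6..1 order)."""
        for name in reversed(GROUP_NAMES):
            if gene_id in getattr(self, name):
                return name
        return None

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.as_dict().items()}


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation statistics for a gene query."""

    term: str
    overlap: int
    term_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float
    rank: int


@dataclass(frozen=True)
class AnnotatedMiRNA:
    """A miRNA with targets and the GO profile inherited from them."""

    mirna_id: str
    targets: frozenset[str]
    go_profile: tuple[EnrichmentResult, ...]
    retained: bool


@dataclass(frozen=True)
class MarkerRecord:
    """One gene in a marker panel, with per-strategy evidence."""

    gene_id: str
    strategies: frozenset[str]
    degree: int
    enrichment_rank: int | None
    cohort_origin: str | None
    expected_direction: str = "unknown"


@dataclass(frozen=True)
class MarkerPanel:
    """Genes surviving the marker-calling policy on one cohort network."""

    cohort: str
    policy: str
    records: tuple[MarkerRecord, ...]

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(r.gene_id for r in self.records)

    def __len__(self) -> int:
        return len(self.records)
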