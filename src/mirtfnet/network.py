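"""Cohort network construction: PPI induction, GO filtering, miRNA overlay."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Set

from mirtfnet.model import (
    ConfigError,
    EDGE_PPI,
    EDGE_REGULATES,
    EDGE_TARGETS,
    GO_CATEGORIES,
    GeneAnnotation,
    NODE_GENE,
    NODE_MIRNA,
    RegulationEdge,
    RegulatoryNetwork,
    TargetEdge,
)

DEFAULT_FILTER_ORDER = (
    "transcription",
    "cell_cycle",
    "cell_organization_biogenesis",
)


@dataclass(frozen=True)
class FilterTrace:
    """Node/edge counts recorded after each sequential filter step."""

    initial_nodes: int
    initial_edges: int
    steps: tuple[tuple[str, int, int], ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {
            "initial": {"nodes": self.initial_nodes, "edges": self.initial_edges},
            "steps": [
                {"filter": name, "nodes": n, "edges": e}
                for name, n, e in self.steps
            ],
        }


def build_induced_network(
    seed_genes: Set[str],
    ppi: Iterable[tuple[str, str]],
    cohort: str = "common",
    depth: int = 1,
) -> RegulatoryNetwork:
    """Expand seed genes by ``depth`` hops of PPI neighbors and induce edges.

    Nodes are the seeds plus every gene reachable within ``depth`` PPI
    hops; edges are all PPI edges with both endpoints in the node set.
    Seeds are kept even when isolated.
    """
    if not seed_genes:
        raise ValueError("seed_genes must be non-empty")
    if depth < 0:
        raise ConfigError("depth must be >= 0")
    ppi = [(min(a, b), max(a, b)) for a, b in ppi]
    adjacency: dict[str, set[str]] = {}
    for a, b in ppi:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    nodes = set(seed_genes)
    frontier = set(seed_genes)
    for _ in range(depth):
        frontier = {
            n for f in frontier for n in adjacency.get(f, ()) if n not in nodes
        }
        if not frontier:
            break
        nodes |= frontier

    net = RegulatoryNetwork(cohort)
    for gene in nodes:
        net.add_node(gene, NODE_GENE)
    for a, b in ppi:
        if a in nodes and b in nodes:
            net.add_edge(a, b, EDGE_PPI)
    return net


def apply_go_filters(
    net: RegulatoryNetwork,
    annotations: Iterable[GeneAnnotation],
    filters: Sequence[str] = DEFAULT_FILTER_ORDER,
) -> tuple[RegulatoryNetwork, FilterTrace]:
    """Sequentially retain gene nodes annotated to each category.

    miRNA nodes are exempt; edges touching a removed node are dropped.
    The final gene set is order-invariant (set intersection commutes) but
    the intermediate trace is not.
    """
    if not filters:
        raise ConfigError("filters must be non-empty")
    for name in filters:
        if name not in GO_CATEGORIES:
            raise ConfigError(f"unknown GO category {name!r}")
    genes_by_category: dict[str, set[str]] = {}
    for ann in annotations:
        genes_by_category.setdefault(ann.go_category, set()).add(ann.gene_id)

    current = net.copy()
    steps: list[tuple[str, int, int]] = []
    for name in filters:
        allowed = genes_by_category.get(name, set())
        for gene in sorted(current.gene_nodes()):
            if gene not in allowed:
                current.remove_node(gene)
        steps.append((name, current.n_nodes(), current.n_edges()))
    trace = FilterTrace(
        initial_nodes=net.n_nodes(),
        initial_edges=net.n_edges(),
        steps=tuple(steps),
    )
    return current, trace


def overlay_regulation(
    net: RegulatoryNetwork,
    regulation: Iterable[RegulationEdge],
    targets: Iterable[TargetEdge],
    cohort_mirnas: Set[str],
) -> RegulatoryNetwork:
    """Overlay cohort miRNAs onto a GO-filtered gene network.

    A miRNA joins the network when it targets at least one gene node
    (directed ``targets`` edge, miRNA -> gene) or is regulated by one
    (directed ``regulates`` edge, gene -> miRNA).  Gene nodes are never
    removed; where both edge kinds meet, miRNA-TF-miRNA and TF-miRNA-TF
    paths arise.
    """
    out = net.copy()
    genes = net.gene_nodes()
    target_hits = [
        e
        for e in targets
        if e.mirna_id in cohort_mirnas and e.gene_id in genes and e.validated
    ]
    regulation_hits = [
        e
        for e in regulation
        if e.mirna_id in cohort_mirnas and e.tf_id in genes
    ]
    for mirna in sorted(
        {e.mirna_id for e in target_hits} | {e.mirna_id for e in regulation_hits}
    ):
        out.add_node(mirna, NODE_MIRNA)
    for e in target_hits:
        out.add_edge(e.mirna_id, e.gene_id, EDGE_TARGETS)
    for e in regulation_hits:
        out.add_edge(e.tf_id, e.mirna_id, EDGE_REGULATES)
    return out


def count_feedforward_loops(net: RegulatoryNetwork) -> int:
    """Count (TF a, miRNA m, TF b) triples closing a feed-forward loop.

    A loop requires a ``regulates`` edge a -> m, a ``targets`` edge m -> b,
    and a PPI edge between a and b.
    """
    regulates: dict[str, set[str]] = {}
    targets_of: dict[str, set[str]] = {}
    ppi: set[tuple[str, str]] = set()
    for s, t, kind in net.edges:
        if kind == EDGE_REGULATES:
            regulates.setdefault(t, set()).add(s)  # mirna -> regulators
        elif kind == EDGE_TARGETS:
            targets_of.setdefault(s, set()).add(t)  # mirna -> targeted genes
        else:
            ppi.add((s, t))
    count = 0
    for mirna, regulators in regulates.items():
        for a in regulators:
            for b in targets_of.get(mirna, ()):
                if a != b and (min(a, b), max(a, b)) in ppi:
                    count += 1
    return count
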