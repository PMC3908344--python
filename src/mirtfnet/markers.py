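"""Network subtraction, strategy scoring and marker-panel calling."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Set

import networkx as nx

from mirtfnet.annotation import hypergeom_enrich
from mirtfnet.model import (
    ConfigError,
    GeneGroupClassification,
    MarkerPanel,
    MarkerRecord,
    RegulatoryNetwork,
)

#: groups whose members the published procedure promotes to the panel
PANEL_GROUPS = ("NSCLC_specific", "general_specific")


def classify_genes(
    net_A: RegulatoryNetwork,
    net_B: RegulatoryNetwork,
    net_C: RegulatoryNetwork,
) -> GeneGroupClassification:
    """Six-way gene classification by subtracting the three cohort networks.

    A is the NSCLC network, B the SCLC network, C the common (general-path)
    network.  ``unique_SCLC`` is the SCLC network's gene set: the schema
    presumes the observed containment B <= A, under which groups 1-3
    coincide whenever B is also contained in C.  miRNA nodes are excluded.
    """
    a = net_A.gene_nodes()
    b = net_B.gene_nodes()
    c = net_C.gene_nodes()
    return GeneGroupClassification(
        unique_SCLC=b,
        common_SCLC_NSCLC=a & b,
        common_all=a & b & c,
        common_NSCLC_general=(a & c) - b,
        NSCLC_specific=a - (b | c),
        general_specific=c - (a | b),
    )


def containment_check(
    net_sub: RegulatoryNetwork, net_super: RegulatoryNetwork
) -> tuple[bool, frozenset[str]]:
    """Gene-set containment with the offending genes as witness."""
    witness = net_sub.gene_nodes() - net_super.gene_nodes()
    return (not witness, frozenset(witness))


def key_nodes(
    net: RegulatoryNetwork, top_k: int | float = 0.25
) -> frozenset[str]:
    """Genes with the highest total degree (all edge types).

    ``top_k`` may be an integer count or a quantile in (0, 1); ties at the
    selection boundary are all included.
    """
    genes = sorted(net.gene_nodes())
    if not genes:
        raise ValueError("network has no gene nodes")
    if isinstance(top_k, float) and not top_k.is_integer():
        if not 0 < top_k < 1:
            raise ConfigError("quantile top_k must be in (0, 1)")
        k = max(1, math.ceil(top_k * len(genes)))
    else:
        k = int(top_k)
        if k <= 0:
            raise ConfigError("top_k must be positive")
    degrees = {g: net.degree(g) for g in genes}
    ranked = sorted(genes, key=lambda g: (-degrees[g], g))
    if k >= len(ranked):
        return frozenset(ranked)
    threshold = degrees[ranked[k - 1]]
    return frozenset(g for g in ranked if degrees[g] >= threshold)


def shortest_path_members(
    net: RegulatoryNetwork, endpoints: Set[str]
) -> frozenset[str]:
    """Genes lying on at least one shortest path between endpoint pairs.

    Distances are unweighted breadth-first over the composite network with
    edge types collapsed; endpoints are members by definition; unreachable
    pairs contribute nothing.
    """
    genes = net.gene_nodes()
    extra = set(endpoints) - genes
    if extra:
        raise ValueError(f"endpoints outside network genes: {sorted(extra)[:5]}")
    endpoints = sorted(endpoints)
    if len(endpoints) < 2:
        return frozenset(endpoints)
    graph = net.to_undirected()
    dist = {
        e: nx.single_source_shortest_path_length(graph, e) for e in endpoints
    }
    members: set[str] = set(endpoints)
    # v is on a shortest s-t path iff d(s,v) + d(v,t) == d(s,t)
    for i, s in enumerate(endpoints):
        for t in endpoints[i + 1 :]:
            d_st = dist[s].get(t)
            if d_st is None:
                continue
            for v in genes:
                dv_s = dist[s].get(v)
                dv_t = dist[t].get(v)
                if dv_s is not None and dv_t is not None and dv_s + dv_t == d_st:
                    members.add(v)
    return frozenset(members)


def enrichment_rank_genes(
    net: RegulatoryNetwork,
    disease_sets: Mapping[str, Set[str]],
    universe: Set[str],
    top_n: int = 10,
    alpha: float = 0.05,
) -> tuple[frozenset[str], dict[str, int]]:
    """Rank network genes by the best q-value among disease sets.

    Each network gene found in at least one tested disease set is scored by
    the minimum q-value over the sets containing it; the ``top_n`` genes by
    score are returned (boundary ties included) together with the dense
    1-based rank of every scored gene.
    """
    if not disease_sets:
        raise ValueError("disease_sets must be non-empty")
    if top_n <= 0:
        raise ConfigError("top_n must be positive")
    query = net.gene_nodes() & set(universe)
    results = hypergeom_enrich(query, disease_sets, universe, alpha)
    q_by_set = {r.term: r.q_value for r in results}
    scores: dict[str, float] = {}
    for name, members in disease_sets.items():
        if name not in q_by_set:
            continue
        for gene in set(members) & query:
            q = q_by_set[name]
            if gene not in scores or q < scores[gene]:
                scores[gene] = q
    if not scores:
        return frozenset(), {}
    ordered = sorted(scores, key=lambda g: (scores[g], g))
    ranks: dict[str, int] = {}
    rank = 0
    prev: float | None = None
    for gene in ordered:
        if prev is None or scores[gene] > prev:
            rank += 1
            prev = scores[gene]
        ranks[gene] = rank
    if top_n >= len(ordered):
        return frozenset(ordered), ranks
    threshold = scores[ordered[top_n - 1]]
    selected = frozenset(g for g in ordered if scores[g] <= threshold)
    return selected, ranks


@dataclass(frozen=True)
class GeneScore:
    """Per-gene evidence from the three prioritization strategies."""

    degree: int
    is_key_node: bool
    on_shortest_path: bool
    enrichment_rank: int | None
    in_enrichment_top: bool

    @property
    def strategies(self) -> frozenset[str]:
        flags = set()
        if self.is_key_node:
            flags.add("key_node")
        if self.on_shortest_path:
            flags.add("shortest_path")
        if self.in_enrichment_top:
            flags.add("enrichment_rank")
        return frozenset(flags)


def compute_strategy_scores(
    net: RegulatoryNetwork,
    disease_sets: Mapping[str, Set[str]],
    universe: Set[str],
    key_top: int | float = 0.25,
    top_n: int = 10,
    endpoints: Set[str] | None = None,
    alpha: float = 0.05,
) -> dict[str, GeneScore]:
    """Score every gene of ``net`` under the three strategies.

    Shortest-path endpoints default to the key-node set.
    """
    hubs = key_nodes(net, key_top)
    if endpoints is None:
        endpoints = hubs
    path_members = shortest_path_members(net, endpoints)
    top_enriched, ranks = enrichment_rank_genes(
        net, disease_sets, universe, top_n, alpha
    )
    return {
        gene: GeneScore(
            degree=net.degree(gene),
            is_key_node=gene in hubs,
            on_shortest_path=gene in path_members,
            enrichment_rank=ranks.get(gene),
            in_enrichment_top=gene in top_enriched,
        )
        for gene in sorted(net.gene_nodes())
    }


def call_markers(
    scores: Mapping[str, GeneScore],
    classification: GeneGroupClassification,
    policy: str = "intersection",
    cohort: str = "common",
) -> MarkerPanel:
    """Call the marker panel from per-gene strategy scores.

    ``intersection`` requires all three strategy flags; ``majority``
    requires at least two.  Expression direction is not predicted here, so
    every record carries ``expected_direction="unknown"``.
    """
    if policy not in ("intersection", "majority"):
        raise ConfigError(f"unknown policy {policy!r}")
    needed = 3 if policy == "intersection" else 2
    records = []
    for gene in sorted(scores):
        score = scores[gene]
        if len(score.strategies) >= needed:
            records.append(
                MarkerRecord(
                    gene_id=gene,
                    strategies=score.strategies,
                    degree=score.degree,
                    enrichment_rank=score.enrichment_rank,
                    cohort_origin=classification.group_of(gene),
                )
            )
    return MarkerPanel(cohort=cohort, policy=policy, records=tuple(records))


def select_panel_genes(
    panels: Iterable[MarkerPanel],
    groups: tuple[str, ...] = PANEL_GROUPS,
) -> frozenset[str]:
    """Combine per-cohort panels, keeping subtype- and path-specific genes."""
    out: set[str] = set()
    for panel in panels:
        for record in panel.records:
            if record.cohort_origin in groups:
                out.add(record.gene_id)
    return frozenset(out)
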