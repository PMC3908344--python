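"""End-to-end orchestration: associations -> networks -> marker panel."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Set

from mirtfnet import annotation as ann
from mirtfnet import markers as mk
from mirtfnet import network as nw
from mirtfnet.model import (
    GeneAnnotation,
    GeneGroupClassification,
    MarkerPanel,
    MiRNAAssociation,
    RegulationEdge,
    RegulatoryNetwork,
    TargetEdge,
)
from mirtfnet.partition import PartitionResult, partition_mirnas, partition_report


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-stage knobs; every stage is deterministic given these."""

    alpha: float = 0.05
    whitelist: frozenset[str] = ann.DEFAULT_WHITELIST
    filter_order: tuple[str, ...] = nw.DEFAULT_FILTER_ORDER
    neighbor_depth: int = 1
    key_top: float | int = 0.25
    enrichment_top_n: int = 10
    policy: str = "intersection"


@dataclass
class PipelineResult:
    """All stage artifacts of one pipeline run."""

    partition: PartitionResult
    networks: dict[str, RegulatoryNetwork]
    traces: dict[str, nw.FilterTrace]
    classification: GeneGroupClassification
    containment: tuple[bool, frozenset[str]]
    panels: dict[str, MarkerPanel]
    panel_genes: frozenset[str]
    retained_mirnas: dict[str, frozenset[str]] = field(default_factory=dict)
    ffl_counts: dict[str, int] = field(default_factory=dict)


def _cohort_network(
    cohort: str,
    mirna_ids: Set[str],
    targets: Sequence[TargetEdge],
    annotations: Sequence[GeneAnnotation],
    universe: Set[str],
    ppi: Sequence[tuple[str, str]],
    regulation: Sequence[RegulationEdge],
    cfg: PipelineConfig,
) -> tuple[RegulatoryNetwork, nw.FilterTrace, frozenset[str]]:
    annotated = ann.annotate_mirnas(
        mirna_ids, targets, annotations, universe, cfg.alpha, cfg.whitelist
    )
    retained, pooled = ann.filter_cohort_mirnas(annotated)
    retained_ids = frozenset(r.mirna_id for r in retained)
    if not pooled:
        empty = RegulatoryNetwork(cohort)
        return empty, nw.FilterTrace(0, 0), retained_ids
    induced = nw.build_induced_network(pooled, ppi, cohort, cfg.neighbor_depth)
    filtered, trace = nw.apply_go_filters(induced, annotations, cfg.filter_order)
    composite = nw.overlay_regulation(filtered, regulation, targets, retained_ids)
    return composite, trace, retained_ids


def run_pipeline(
    associations: Iterable[MiRNAAssociation],
    targets: Iterable[TargetEdge],
    annotations: Iterable[GeneAnnotation],
    ppi: Iterable[tuple[str, str]],
    regulation: Iterable[RegulationEdge],
    disease_sets: Mapping[str, Set[str]] | None = None,
    cfg: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the whole marker-discovery pipeline on in-memory tables.

    Cohort networks are built from the pooled targets of annotation-retained
    miRNAs; the NSCLC and common networks are scored under the three
    strategies and subtype-/path-specific genes passing the calling policy
    form the final panel.
    """
    targets = list(targets)
    annotations = list(annotations)
    ppi = list(ppi)
    regulation = list(regulation)

    result = partition_mirnas(associations)
    universe = (
        {a.gene_id for a in annotations}
        | {t.gene_id for t in targets}
        | {g for edge in ppi for g in edge}
    )

    cohort_mirnas = {
        "NSCLC": result.unique_A,
        "SCLC": result.unique_B,
        "common": result.common,
    }
    networks: dict[str, RegulatoryNetwork] = {}
    traces: dict[str, nw.FilterTrace] = {}
    retained: dict[str, frozenset[str]] = {}
    for cohort, ids in cohort_mirnas.items():
        net, trace, kept = _cohort_network(
            cohort, ids, targets, annotations, universe, ppi, regulation, cfg
        )
        networks[cohort] = net
        traces[cohort] = trace
        retained[cohort] = kept

    classification = mk.classify_genes(
        networks["NSCLC"], networks["SCLC"], networks["common"]
    )
    containment = mk.containment_check(networks["SCLC"], networks["NSCLC"])

    panels: dict[str, MarkerPanel] = {}
    for cohort in ("NSCLC", "common"):
        net = networks[cohort]
        if not net.gene_nodes():
            panels[cohort] = MarkerPanel(cohort, cfg.policy, ())
            continue
        scores = compute_scores_optional_enrichment(
            net, disease_sets, universe, cfg
        )
        panels[cohort] = mk.call_markers(
            scores, classification, cfg.policy, cohort
        )
    panel_genes = mk.select_panel_genes(panels.values())

    ffl = {c: nw.count_feedforward_loops(n) for c, n in networks.items()}
    return PipelineResult(
        partition=result,
        networks=networks,
        traces=traces,
        classification=classification,
        containment=containment,
        panels=panels,
        panel_genes=panel_genes,
        retained_mirnas=retained,
        ffl_counts=ffl,
    )


def compute_scores_optional_enrichment(
    net: RegulatoryNetwork,
    disease_sets: Mapping[str, Set[str]] | None,
    universe: Set[str],
    cfg: PipelineConfig,
) -> dict[str, mk.GeneScore]:
    """Strategy scores; without disease sets the enrichment strategy is
    inactive and counts as satisfied for every gene."""
    if disease_sets:
        return mk.compute_strategy_scores(
            net,
            disease_sets,
            universe,
            key_top=cfg.key_top,
            top_n=cfg.enrichment_top_n,
            alpha=cfg.alpha,
        )
    hubs = mk.key_nodes(net, cfg.key_top)
    members = mk.shortest_path_members(net, hubs)
    return {
        gene: mk.GeneScore(
            degree=net.degree(gene),
            is_key_node=gene in hubs,
            on_shortest_path=gene in members,
            enrichment_rank=None,
            in_enrichment_top=True,
        )
        for gene in sorted(net.gene_nodes())
    }


def build_report(result: PipelineResult, cfg: PipelineConfig, seed: int | None = None) -> dict:
    """Consolidated machine-readable run report."""
    report: dict = {
        "schema_version": 1,
        "partition": partition_report(result.partition),
        "networks": {
            c: {
                "genes": sorted(n.gene_nodes()),
                "n_genes": len(n.gene_nodes()),
                "n_mirnas": len(n.mirna_nodes()),
                "n_edges": n.n_edges(),
            }
            for c, n in result.networks.items()
        },
        "filter_traces": {c: t.as_dict() for c, t in result.traces.items()},
        "classification": {
            "groups": {
                name: sorted(genes)
                for name, genes in result.classification.as_dict().items()
            },
            "sizes": result.classification.sizes(),
        },
        "containment_SCLC_in_NSCLC": {
            "holds": result.containment[0],
            "witness": sorted(result.containment[1]),
        },
        "panels": {
            c: [
                {
                    "gene_id": r.gene_id,
                    "strategies": sorted(r.strategies),
                    "degree": r.degree,
                    "enrichment_rank": r.enrichment_rank,
                    "cohort_origin": r.cohort_origin,
                    "expected_direction": r.expected_direction,
                }
                for r in p.records
            ]
            for c, p in result.panels.items()
        },
        "panel_genes": sorted(result.panel_genes),
        "feedforward_loops": dict(result.ffl_counts),
        "retained_mirnas": {
            c: sorted(m) for c, m in result.retained_mirnas.items()
        },
        "config": {
            "alpha": cfg.alpha,
            "whitelist": sorted(cfg.whitelist),
            "filter_order": list(cfg.filter_order),
            "neighbor_depth": cfg.neighbor_depth,
            "key_top": cfg.key_top,
            "enrichment_top_n": cfg.enrichment_top_n,
            "policy": cfg.policy,
        },
    }
    if seed is not None:
        report["seed"] = seed
    return report
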