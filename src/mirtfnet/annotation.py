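"""Reverse annotation: GO profiles for miRNAs via enrichment of their targets.

A miRNA inherits GO terms from the annotations of its validated targets.
Over-representation is scored with an upper-tail hypergeometric test and
Benjamini-Hochberg correction; a miRNA is retained when at least one term
from a whitelisted category is significant.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Set

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from mirtfnet.model import (
    AnnotatedMiRNA,
    EnrichmentResult,
    GeneAnnotation,
    TargetEdge,
)

DEFAULT_ALPHA = 0.05
DEFAULT_WHITELIST = frozenset(
    {"transcription", "cell_cycle", "cell_organization_biogenesis"}
)


def hypergeom_enrich(
    query: Set[str],
    term_sets: Mapping[str, Set[str]],
    universe: Set[str],
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of ``query`` against term sets.

    For each term, ``p = P(X >= overlap)`` where X counts term genes in a
    draw of ``len(query)`` genes from ``len(universe)``; q-values are
    Benjamini-Hochberg over all tested terms.  Results are sorted by
    ascending p then term id; ranks are 1-based and dense (ties share a
    rank).  Terms with no gene in the universe are not tested.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query:
        return []
    extra = set(query) - set(universe)
    if extra:
        raise ValueError(f"query genes outside universe: {sorted(extra)[:5]}")

    m = len(universe)
    n_query = len(query)
    rows: list[tuple[str, int, int, float]] = []
    for term in term_sets:
        term_genes = set(term_sets[term]) & set(universe)
        if not term_genes:
            continue
        overlap = len(term_genes & set(query))
        p = float(hypergeom.sf(overlap - 1, m, len(term_genes), n_query))
        p = min(max(p, 0.0), 1.0)
        rows.append((term, overlap, len(term_genes), p))
    if not rows:
        return []

    rows.sort(key=lambda r: (r[3], r[0]))
    _, q_values, _, _ = multipletests(
        [r[3] for r in rows], alpha=alpha, method="fdr_bh"
    )
    results: list[EnrichmentResult] = []
    rank = 0
    prev_p: float | None = None
    for (term, overlap, term_size, p), q in zip(rows, q_values):
        if prev_p is None or p > prev_p:
            rank += 1
            prev_p = p
        results.append(
            EnrichmentResult(
                term=term,
                overlap=overlap,
                term_size=term_size,
                query_size=n_query,
                universe_size=m,
                p_value=p,
                q_value=min(max(float(q), 0.0), 1.0),
                rank=rank,
            )
        )
    return results


def term_sets_from_annotations(
    annotations: Iterable[GeneAnnotation],
) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Build term -> gene-set and term -> category-set maps."""
    genes: dict[str, set[str]] = {}
    categories: dict[str, set[str]] = {}
    for ann in annotations:
        genes.setdefault(ann.go_term, set()).add(ann.gene_id)
        categories.setdefault(ann.go_term, set()).add(ann.go_category)
    return (
        {t: frozenset(g) for t, g in genes.items()},
        {t: frozenset(c) for t, c in categories.items()},
    )


def profile_is_retained(
    profile: Iterable[EnrichmentResult],
    term_categories: Mapping[str, Set[str]],
    whitelist: Set[str],
    alpha: float,
) -> bool:
    return any(
        r.q_value <= alpha
        and term_categories.get(r.term, frozenset()) & set(whitelist)
        for r in profile
    )


def annotate_mirna(
    mirna_id: str,
    target_table: Iterable[TargetEdge],
    annotations: Iterable[GeneAnnotation],
    universe: Set[str],
    alpha: float = DEFAULT_ALPHA,
    whitelist: Set[str] = DEFAULT_WHITELIST,
) -> AnnotatedMiRNA:
    """Assign a GO profile to one miRNA from its validated targets."""
    targets = {
        e.gene_id
        for e in target_table
        if e.mirna_id == mirna_id and e.validated
    }
    if not targets:
        raise ValueError(f"miRNA {mirna_id!r} has no validated targets")
    annotations = list(annotations)
    term_sets, term_categories = term_sets_from_annotations(annotations)
    profile = hypergeom_enrich(
        targets & set(universe), term_sets, universe, alpha
    )
    retained = profile_is_retained(profile, term_categories, whitelist, alpha)
    return AnnotatedMiRNA(
        mirna_id=mirna_id,
        targets=frozenset(targets),
        go_profile=tuple(profile),
        retained=retained,
    )


def annotate_mirnas(
    mirna_ids: Iterable[str],
    target_table: Iterable[TargetEdge],
    annotations: Iterable[GeneAnnotation],
    universe: Set[str],
    alpha: float = DEFAULT_ALPHA,
    whitelist: Set[str] = DEFAULT_WHITELIST,
) -> list[AnnotatedMiRNA]:
    """Annotate many miRNAs; miRNAs without targets are skipped."""
    target_table = list(target_table)
    annotations = list(annotations)
    with_targets = {e.mirna_id for e in target_table if e.validated}
    return [
        annotate_mirna(m, target_table, annotations, universe, alpha, whitelist)
        for m in sorted(set(mirna_ids) & with_targets)
    ]


def filter_cohort_mirnas(
    annotated: Iterable[AnnotatedMiRNA],
    whitelist: Set[str] | None = None,
    term_categories: Mapping[str, Set[str]] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[AnnotatedMiRNA], frozenset[str]]:
    """Keep whitelisted miRNAs and pool the targets of the survivors.

    With ``whitelist`` and ``term_categories`` given, the retained flag is
    recomputed; otherwise the flag carried on each record is trusted.
    """
    if whitelist is not None and not whitelist:
        raise ValueError("whitelist must be non-empty when given")
    retained: list[AnnotatedMiRNA] = []
    for record in annotated:
        if whitelist is not None and term_categories is not None:
            keep = profile_is_retained(
                record.go_profile, term_categories, whitelist, alpha
            )
        else:
            keep = record.retained
        if keep:
            retained.append(record)
    pooled = frozenset().union(*(r.targets for r in retained)) if retained else frozenset()
    return retained, pooled
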