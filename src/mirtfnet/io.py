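"""Readers and writers for the TSV / GMT / SIF dialects used by the pipeline.

All files are UTF-8 with LF line endings.  Tabular inputs require a header
row.  Gene identifiers are treated as opaque strings but a single
normalization pass (strip + uppercase) is applied at load and logged;
miRNA identifiers are stripped only, preserving case.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping

from mirtfnet.model import (
    CONFLICT,
    COHORTS,
    DIFFERENTIAL,
    DIRECTIONS,
    EDGE_PPI,
    EDGE_REGULATES,
    EDGE_TARGETS,
    FormatError,
    GeneAnnotation,
    MiRNAAssociation,
    NODE_GENE,
    NODE_MIRNA,
    RegulationEdge,
    RegulatoryNetwork,
    TargetEdge,
)

logger = logging.getLogger(__name__)

_ASSOC_COLUMNS = ("mirna_id", "subtype", "direction", "source")
_DIRECTION_TOKENS = set(DIRECTIONS) | {DIFFERENTIAL, CONFLICT}


def normalize_gene(gene_id: str) -> str:
    return gene_id.strip().upper()


def normalize_mirna(mirna_id: str) -> str:
    return mirna_id.strip()


def _open_rows(path: str | Path, required: tuple[str, ...]) -> tuple[list[dict], list[str]]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        header = reader.fieldnames
        if header is None:
            raise FormatError(f"{path}: empty file, expected a header row")
        missing = [c for c in required if c not in header]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        return list(reader), list(header)


def read_association_table(path: str | Path) -> list[MiRNAAssociation]:
    """Load miRNA-cohort associations, merging duplicate rows.

    Duplicate ``(mirna_id, subtype)`` rows are merged; when their directions
    conflict the merged direction is recorded as ``conflict`` so it is
    counted in neither the up nor the down tally downstream.
    """
    rows, _ = _open_rows(path, _ASSOC_COLUMNS)
    merged: dict[str, dict[str, str]] = {}
    sources: dict[str, list[str]] = {}
    order: list[str] = []
    for lineno, row in enumerate(rows, start=2):
        mirna = normalize_mirna(row["mirna_id"] or "")
        subtype = (row["subtype"] or "").strip()
        direction = (row["direction"] or "").strip().lower()
        if not mirna:
            raise FormatError(f"{path}: line {lineno}: empty mirna_id")
        if subtype not in COHORTS:
            raise FormatError(
                f"{path}: line {lineno}: unknown subtype {subtype!r} "
                f"(expected one of {', '.join(COHORTS)})"
            )
        if direction not in _DIRECTION_TOKENS:
            raise FormatError(
                f"{path}: line {lineno}: unknown direction {direction!r}"
            )
        if mirna not in merged:
            merged[mirna] = {}
            sources[mirna] = []
            order.append(mirna)
        prior = merged[mirna].get(subtype)
        if prior is None or prior == direction:
            merged[mirna][subtype] = direction
        else:
            merged[mirna][subtype] = CONFLICT
        src = (row.get("source") or "").strip()
        if src and src not in sources[mirna]:
            sources[mirna].append(src)
    return [
        MiRNAAssociation(
            mirna_id=m,
            directions=dict(merged[m]),
            source=";".join(sources[m]),
        )
        for m in order
    ]


def write_association_table(
    associations: Iterable[MiRNAAssociation], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("mirna_id\tsubtype\tdirection\tsource\n")
        for assoc in associations:
            for subtype in sorted(assoc.directions):
                handle.write(
                    f"{assoc.mirna_id}\t{subtype}\t"
                    f"{assoc.directions[subtype]}\t{assoc.source}\n"
                )


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Load a GMT file: name, description, then tab-separated genes."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name = fields[0].strip()
            if name in sets:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate set name {name!r}"
                )
            genes = frozenset(
                normalize_gene(g) for g in fields[2:] if g.strip()
            )
            sets[name] = genes
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    path = Path(path)
    descriptions = descriptions or {}
    with path.open("w", encoding="utf-8", newline="\n") as handle:
        for name in sets:
            desc = descriptions.get(name, "na")
            genes = "\t".join(sorted(sets[name]))
            handle.write(f"{name}\t{desc}\t{genes}\n")


def read_target_table(path: str | Path) -> list[TargetEdge]:
    """Load miRNA -> target edges; duplicate pairs collapse to one edge."""
    rows, header = _open_rows(path, ("mirna_id", "gene_id"))
    has_validated = "validated" in header
    seen: dict[tuple[str, str], TargetEdge] = {}
    for lineno, row in enumerate(rows, start=2):
        mirna = normalize_mirna(row["mirna_id"] or "")
        gene = normalize_gene(row["gene_id"] or "")
        if not mirna or not gene:
            raise FormatError(f"{path}: line {lineno}: empty identifier")
        validated = True
        if has_validated:
            token = (row["validated"] or "true").strip().lower()
            validated = token in ("1", "true", "yes", "y")
        key = (mirna, gene)
        if key not in seen:
            seen[key] = TargetEdge(mirna, gene, validated)
    return list(seen.values())


def write_target_table(edges: Iterable[TargetEdge], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("mirna_id\tgene_id\tvalidated\n")
        for e in edges:
            handle.write(
                f"{e.mirna_id}\t{e.gene_id}\t{'true' if e.validated else 'false'}\n"
            )


def read_annotation_table(
    path: str | Path,
    category_map: Mapping[str, str] | None = None,
) -> list[GeneAnnotation]:
    """Load flat gene -> GO-term annotations.

    The category comes from an explicit ``go_category`` column when present,
    otherwise from ``category_map`` (term -> category), defaulting to
    ``other``.  Duplicate (gene, term) pairs collapse to the first row.
    """
    rows, header = _open_rows(path, ("gene_id", "go_term"))
    has_category = "go_category" in header
    category_map = category_map or {}
    seen: dict[tuple[str, str], GeneAnnotation] = {}
    for lineno, row in enumerate(rows, start=2):
        gene = normalize_gene(row["gene_id"] or "")
        term = (row["go_term"] or "").strip()
        if not gene or not term:
            raise FormatError(f"{path}: line {lineno}: empty identifier")
        if has_category and (row["go_category"] or "").strip():
            category = row["go_category"].strip()
        else:
            category = category_map.get(term, "other")
        key = (gene, term)
        if key not in seen:
            try:
                seen[key] = GeneAnnotation(gene, term, category)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return list(seen.values())


def write_annotation_table(
    annotations: Iterable[GeneAnnotation], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("gene_id\tgo_term\tgo_category\n")
        for a in annotations:
            handle.write(f"{a.gene_id}\t{a.go_term}\t{a.go_category}\n")


def read_ppi_table(path: str | Path) -> list[tuple[str, str]]:
    """Load undirected gene-gene edges, canonicalized and de-duplicated."""
    rows, _ = _open_rows(path, ("gene_a", "gene_b"))
    seen: set[tuple[str, str]] = set()
    out: list[tuple[str, str]] = []
    for lineno, row in enumerate(rows, start=2):
        a = normalize_gene(row["gene_a"] or "")
        b = normalize_gene(row["gene_b"] or "")
        if not a or not b:
            raise FormatError(f"{path}: line {lineno}: empty identifier")
        if a == b:
            continue  # self-interactions carry no network information here
        edge = (min(a, b), max(a, b))
        if edge not in seen:
            seen.add(edge)
            out.append(edge)
    return out


def write_ppi_table(
    edges: Iterable[tuple[str, str]], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("gene_a\tgene_b\n")
        for a, b in edges:
            a, b = min(a, b), max(a, b)
            handle.write(f"{a}\t{b}\n")


def read_regulation_table(path: str | Path) -> list[RegulationEdge]:
    rows, header = _open_rows(path, ("tf_id", "mirna_id"))
    has_mode = "mode" in header
    seen: dict[tuple[str, str], RegulationEdge] = {}
    for lineno, row in enumerate(rows, start=2):
        tf = normalize_gene(row["tf_id"] or "")
        mirna = normalize_mirna(row["mirna_id"] or "")
        if not tf or not mirna:
            raise FormatError(f"{path}: line {lineno}: empty identifier")
        mode = "unknown"
        if has_mode and (row["mode"] or "").strip():
            mode = row["mode"].strip().lower()
        key = (tf, mirna)
        if key not in seen:
            try:
                seen[key] = RegulationEdge(tf, mirna, mode)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return list(seen.values())


def write_regulation_table(
    edges: Iterable[RegulationEdge], path: str | Path
) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        handle.write("tf_id\tmirna_id\tmode\n")
        for e in edges:
            handle.write(f"{e.tf_id}\t{e.mirna_id}\t{e.mode}\n")


def write_network_sif(net: RegulatoryNetwork, path: str | Path) -> None:
    """Write a network in SIF: ``source<TAB>edge_type<TAB>target``.

    ppi edges are emitted once in canonical (lexicographic) order; nodes
    without any edge are emitted as single-column lines.
    """
    lines: list[str] = []
    touched: set[str] = set()
    for source, target, edge_type in sorted(net.edges):
        lines.append(f"{source}\t{edge_type}\t{target}")
        touched.update((source, target))
    for node in sorted(net.nodes):
        if node not in touched:
            lines.append(node)
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        for line in lines:
            handle.write(line + "\n")


def read_network_sif(path: str | Path, cohort: str = "common") -> RegulatoryNetwork:
    """Read a SIF network written by :func:`write_network_sif`.

    Node types are inferred from edge semantics: the source of a ``targets``
    edge and the target of a ``regulates`` edge are miRNA nodes; every other
    node is a gene.  An isolated miRNA node is therefore indistinguishable
    from a gene in this dialect and reads back as a gene.
    """
    path = Path(path)
    nodes: dict[str, str] = {}
    edges: list[tuple[str, str, str]] = []
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                nodes.setdefault(fields[0], NODE_GENE)
                continue
            if len(fields) != 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected 1 or 3 fields, "
                    f"got {len(fields)}"
                )
            source, edge_type, target = fields
            if edge_type not in (EDGE_PPI, EDGE_TARGETS, EDGE_REGULATES):
                raise FormatError(
                    f"{path}: line {lineno}: unknown edge type {edge_type!r}"
                )
            if edge_type == EDGE_TARGETS:
                nodes[source] = NODE_MIRNA
                nodes.setdefault(target, NODE_GENE)
            elif edge_type == EDGE_REGULATES:
                nodes.setdefault(source, NODE_GENE)
                nodes[target] = NODE_MIRNA
            else:
                nodes.setdefault(source, NODE_GENE)
                nodes.setdefault(target, NODE_GENE)
            edges.append((source, target, edge_type))
    net = RegulatoryNetwork(cohort)
    for node_id, node_type in nodes.items():
        net.add_node(node_id, node_type)
    for source, target, edge_type in edges:
        net.add_edge(source, target, edge_type)
    return net
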