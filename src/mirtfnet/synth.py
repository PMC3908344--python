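"""Synthetic input bundles with planted subtype-specific marker structure.

The generator emits all six pipeline tables (associations, targets,
annotations, PPI, TF->miRNA regulation, disease gene sets) plus a truth
record.  Planted marker TFs satisfy every marker condition by
construction: annotated to all three whitelisted GO categories, targeted
by three cohort miRNAs, regulating two cohort miRNAs (closing
miRNA-TF-miRNA loops), wired as a within-group PPI clique and
degree-boosted above the non-planted median.  Decoy TFs each fail at
least one condition.  Cohort-specific planted TFs share no PPI edge with
genes reachable from other cohorts' seeds, so one-hop neighbor expansion
cannot leak them across networks; the random PPI background is confined
to filler genes for the same reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from mirtfnet import io
from mirtfnet.model import (
    ConfigError,
    GeneAnnotation,
    MiRNAAssociation,
    RegulationEdge,
    TargetEdge,
)

_WHITELIST_CATEGORIES = (
    "transcription",
    "cell_cycle",
    "cell_organization_biogenesis",
)
#: carriers per planted group: each planted TF is targeted by this many miRNAs
_N_CARRIERS = 3
#: shared genes targeted per shared-carrier miRNA
_SHARED_CHUNK = 3
#: minimum background/filler genes beyond the TF block
_MIN_FILLERS = 12


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic bundle generator."""

    n_mirna_A: int = 10
    n_mirna_B: int = 5
    n_common: int = 8
    targets_per_mirna: int = 4
    n_genes: int = 60
    n_tf: int = 14
    ppi_edge_prob: float = 0.05
    planted_markers_A: int = 3
    planted_markers_general: int = 2
    go_noise_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_mirna_A": self.n_mirna_A,
            "n_mirna_B": self.n_mirna_B,
            "n_common": self.n_common,
            "targets_per_mirna": self.targets_per_mirna,
            "n_genes": self.n_genes,
            "n_tf": self.n_tf,
            "planted_markers_A": self.planted_markers_A,
            "planted_markers_general": self.planted_markers_general,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        for name, value in (
            ("ppi_edge_prob", self.ppi_edge_prob),
            ("go_noise_prob", self.go_noise_prob),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        n_planted = self.planted_markers_A + self.planted_markers_general
        if n_planted > self.n_tf:
            raise ConfigError(
                f"planted markers ({n_planted}) exceed n_tf ({self.n_tf})"
            )
        if self.n_shared < 2:
            raise ConfigError(
                "n_tf leaves fewer than 2 shared TFs after planted markers"
            )
        if self.n_genes < self.n_tf + _MIN_FILLERS:
            raise ConfigError(
                f"n_genes must be >= n_tf + {_MIN_FILLERS} so planted PPI "
                "degree can exceed the non-planted median"
            )
        for name, value in (
            ("planted_markers_A", self.planted_markers_A),
            ("planted_markers_general", self.planted_markers_general),
        ):
            if value == 1:
                raise ConfigError(
                    f"{name} must be 0 or >= 2: a single planted gene "
                    "cannot reach enrichment significance"
                )
        if self.planted_markers_A:
            if self.n_mirna_A < _N_CARRIERS + 1:
                raise ConfigError(
                    f"planted cohort-A markers need n_mirna_A >= {_N_CARRIERS + 1}"
                )
        if self.planted_markers_general:
            if self.n_common < _N_CARRIERS + 1:
                raise ConfigError(
                    f"planted general markers need n_common >= {_N_CARRIERS + 1}"
                )
        if self.targets_per_mirna < 1:
            raise ConfigError("targets_per_mirna must be >= 1")

    @property
    def n_decoys(self) -> int:
        room = self.n_tf - self.planted_markers_A - self.planted_markers_general
        return max(0, min(3, room - 4))

    @property
    def n_shared(self) -> int:
        return (
            self.n_tf
            - self.planted_markers_A
            - self.planted_markers_general
            - self.n_decoys
        )


@dataclass(frozen=True)
class SyntheticBundle:
    """In-memory synthetic input bundle plus the planted-structure truth."""

    config: SyntheticConfig
    associations: tuple[MiRNAAssociation, ...]
    targets: tuple[TargetEdge, ...]
    annotations: tuple[GeneAnnotation, ...]
    ppi: tuple[tuple[str, str], ...]
    regulation: tuple[RegulationEdge, ...]
    disease_sets: Mapping[str, frozenset[str]]
    truth: Mapping[str, object]

    def gene_universe(self) -> frozenset[str]:
        return frozenset(self.truth["universe"])


def _gene_names(cfg: SyntheticConfig) -> dict[str, list[str]]:
    pa, pg = cfg.planted_markers_A, cfg.planted_markers_general
    shared, decoys = cfg.n_shared, cfg.n_decoys
    names = {
        "planted_A": [f"TFA{i + 1:02d}" for i in range(pa)],
        "planted_G": [f"TFG{i + 1:02d}" for i in range(pg)],
        "shared": [f"TFS{i + 1:02d}" for i in range(shared)],
        "decoys": [f"TFD{i + 1:02d}" for i in range(decoys)],
    }
    n_fillers = cfg.n_genes - cfg.n_tf
    fillers = [f"GENE{i + 1:03d}" for i in range(n_fillers)]
    # per-cohort filler pools are disjoint so targeting one cohort's fillers
    # never drags another cohort's planted genes in through PPI adjacency
    chunk = max(2, n_fillers // 4)
    names["fillers_A"] = fillers[:chunk]
    names["fillers_B"] = fillers[chunk : 2 * chunk]
    names["fillers_C"] = fillers[2 * chunk : 3 * chunk]
    names["fillers_bg"] = fillers[3 * chunk :]
    return names


def _mirna_names(cfg: SyntheticConfig) -> dict[str, list[str]]:
    return {
        "A": [f"mir-A{i + 1:02d}" for i in range(cfg.n_mirna_A)],
        "B": [f"mir-B{i + 1:02d}" for i in range(cfg.n_mirna_B)],
        "C": [f"mir-C{i + 1:02d}" for i in range(cfg.n_common)],
    }


def _build_associations(
    cfg: SyntheticConfig, mirnas: dict[str, list[str]]
) -> list[MiRNAAssociation]:
    out = []
    for i, m in enumerate(mirnas["A"]):
        out.append(
            MiRNAAssociation(m, {"NSCLC": "up" if i % 2 == 0 else "down"}, "synthetic")
        )
    for i, m in enumerate(mirnas["B"]):
        out.append(
            MiRNAAssociation(m, {"SCLC": "up" if i % 2 == 0 else "down"}, "synthetic")
        )
    for i, m in enumerate(mirnas["C"]):
        if i % 3 == 2:  # mixed pattern: every third common miRNA differential
            directions = {"NSCLC": "up", "SCLC": "down"}
        else:
            d = "up" if i % 2 == 0 else "down"
            directions = {"NSCLC": d, "SCLC": d}
        out.append(MiRNAAssociation(m, directions, "synthetic"))
    return out


def _cohort_targets(
    planted: list[str],
    shared: list[str],
    fillers: list[str],
    cohort_mirnas: list[str],
    tpm: int,
    rng: np.random.Generator,
    extra_first_shared_carrier: str | None = None,
) -> list[TargetEdge]:
    """Wire one cohort's miRNA -> target edges.

    The first ``_N_CARRIERS`` miRNAs each target every planted gene; the
    following miRNAs cover the shared genes in chunks of ``_SHARED_CHUNK``;
    any remaining miRNAs target fillers only (and will not survive the
    annotation filter).
    """
    edges: list[TargetEdge] = []
    idx = 0
    carriers = _N_CARRIERS if planted else 0
    for m in cohort_mirnas[:carriers]:
        # carriers target exactly the planted set: padding with fillers
        # dilutes the enrichment signal below the retention threshold for
        # small planted groups
        edges += [TargetEdge(m, g) for g in planted]
    idx = carriers
    shared_left = list(shared)
    first_shared_carrier = True
    while shared_left and idx < len(cohort_mirnas):
        m = cohort_mirnas[idx]
        genes = shared_left[:_SHARED_CHUNK]
        shared_left = shared_left[_SHARED_CHUNK:]
        if len(genes) < _SHARED_CHUNK:
            # wrap around so the carrier still sees a strong shared overlap
            genes += [g for g in shared if g not in genes][: _SHARED_CHUNK - len(genes)]
        if first_shared_carrier and extra_first_shared_carrier:
            genes.append(extra_first_shared_carrier)
            first_shared_carrier = False
        genes += _pick_fillers(fillers, tpm - len(genes), rng, exclude=set(genes))
        edges += [TargetEdge(m, g) for g in genes]
        idx += 1
    for m in cohort_mirnas[idx:]:
        genes = _pick_fillers(fillers, max(1, tpm), rng)
        edges += [TargetEdge(m, g) for g in genes]
    return edges


def _pick_fillers(
    pool: list[str],
    k: int,
    rng: np.random.Generator,
    exclude: set[str] | None = None,
) -> list[str]:
    if k <= 0:
        return []
    candidates = [g for g in pool if not exclude or g not in exclude]
    if not candidates:
        return []
    k = min(k, len(candidates))
    picked = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in sorted(picked)]


def _build_annotations(
    cfg: SyntheticConfig,
    names: dict[str, list[str]],
    rng: np.random.Generator,
) -> list[GeneAnnotation]:
    annotations: list[GeneAnnotation] = []

    prefixes = {
        "transcription": "TR",
        "cell_cycle": "CC",
        "cell_organization_biogenesis": "OB",
        "other": "OT",
    }

    def annotate_group(genes: list[str], suffix: str, categories) -> None:
        for cat in categories:
            term = f"TERM_{prefixes[cat]}_{suffix}"
            for g in genes:
                annotations.append(GeneAnnotation(g, term, cat))

    annotate_group(names["planted_A"], "A", _WHITELIST_CATEGORIES)
    annotate_group(names["planted_G"], "G", _WHITELIST_CATEGORIES)
    annotate_group(names["shared"], "S", _WHITELIST_CATEGORIES)
    decoys = names["decoys"]
    weak = decoys[:1]  # passes GO filters, fails degree/targeting conditions
    annotate_group(weak, "D2", _WHITELIST_CATEGORIES)
    annotate_group(decoys[1:], "D1", ("transcription", "other"))
    fillers = (
        names["fillers_A"]
        + names["fillers_B"]
        + names["fillers_C"]
        + names["fillers_bg"]
    )
    for i, g in enumerate(fillers):
        annotations.append(GeneAnnotation(g, f"TERM_OT_F{i % 3}", "other"))

    # spurious annotations: at most one extra random term per gene, so no
    # gene can gain membership of all three whitelisted categories by noise
    term_pool = sorted({a.go_term for a in annotations})
    category_of = {a.go_term: a.go_category for a in annotations}
    existing = {(a.gene_id, a.go_term) for a in annotations}
    all_genes = (
        names["planted_A"]
        + names["planted_G"]
        + names["shared"]
        + decoys
        + fillers
    )
    for g in all_genes:
        if rng.random() < cfg.go_noise_prob:
            term = term_pool[int(rng.integers(len(term_pool)))]
            if (g, term) not in existing:
                annotations.append(GeneAnnotation(g, term, category_of[term]))
                existing.add((g, term))
    return annotations


def _build_ppi(
    cfg: SyntheticConfig,
    names: dict[str, list[str]],
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        if a != b:
            edges.add((min(a, b), max(a, b)))

    for group in ("planted_A", "planted_G"):
        members = names[group]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                add(a, b)
    shared = names["shared"]
    if len(shared) > 1:
        for i, a in enumerate(shared):
            add(a, shared[(i + 1) % len(shared)])
    bg = names["fillers_bg"]
    for decoy in names["decoys"][:1]:
        if bg:
            add(decoy, bg[0])
    # random background confined to filler genes
    fillers = (
        names["fillers_A"] + names["fillers_B"] + names["fillers_C"] + bg
    )
    for i, a in enumerate(fillers):
        for b in fillers[i + 1 :]:
            if rng.random() < cfg.ppi_edge_prob:
                add(a, b)

    # boost planted PPI degree strictly above the non-planted median
    planted = names["planted_A"] + names["planted_G"]
    boost_pool = bg + names["fillers_A"] + names["fillers_B"] + names["fillers_C"]
    for _ in range(len(boost_pool)):
        degree: dict[str, int] = {}
        for a, b in edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        all_genes = planted + names["shared"] + names["decoys"] + fillers
        non_planted = [g for g in all_genes if g not in planted]
        median = float(np.median([degree.get(g, 0) for g in non_planted]))
        lagging = [g for g in planted if degree.get(g, 0) <= median]
        if not lagging:
            break
        grew = False
        for g in lagging:
            for partner in boost_pool:
                if (min(g, partner), max(g, partner)) not in edges:
                    add(g, partner)
                    grew = True
                    break
        if not grew:
            raise ConfigError(
                "cannot boost planted PPI degree above the non-planted "
                "median; increase n_genes or lower ppi_edge_prob"
            )
    else:
        raise ConfigError(
            "planted PPI degree boost did not converge; increase n_genes"
        )
    return sorted(edges)


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate a complete synthetic bundle with planted marker structure."""
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_targets = np.random.default_rng(streams[0])
    rng_annotations = np.random.default_rng(streams[1])
    rng_ppi = np.random.default_rng(streams[2])

    names = _gene_names(cfg)
    mirnas = _mirna_names(cfg)
    associations = _build_associations(cfg, mirnas)

    decoy_weak = names["decoys"][:1]
    targets: list[TargetEdge] = []
    targets += _cohort_targets(
        names["planted_A"],
        names["shared"],
        names["fillers_A"],
        mirnas["A"],
        cfg.targets_per_mirna,
        rng_targets,
        extra_first_shared_carrier=decoy_weak[0] if decoy_weak else None,
    )
    targets += _cohort_targets(
        [], names["shared"], names["fillers_B"], mirnas["B"],
        cfg.targets_per_mirna, rng_targets,
    )
    targets += _cohort_targets(
        names["planted_G"], names["shared"], names["fillers_C"], mirnas["C"],
        cfg.targets_per_mirna, rng_targets,
    )

    annotations = _build_annotations(cfg, names, rng_annotations)
    ppi = _build_ppi(cfg, names, rng_ppi)

    regulation: list[RegulationEdge] = []
    for g in names["planted_A"]:
        for m in mirnas["A"][:2]:
            regulation.append(RegulationEdge(g, m, "activates"))
    for g in names["planted_G"]:
        for m in mirnas["C"][:2]:
            regulation.append(RegulationEdge(g, m, "activates"))
    for g in names["shared"][:1]:
        for m in mirnas["A"][:1] + mirnas["C"][:1]:
            regulation.append(RegulationEdge(g, m, "represses"))

    disease_sets: dict[str, frozenset[str]] = {}
    if names["planted_A"]:
        disease_sets["disease_NSCLC"] = frozenset(names["planted_A"])
    if names["planted_G"]:
        disease_sets["disease_general"] = frozenset(names["planted_G"])
    if names["shared"]:
        disease_sets["disease_core"] = frozenset(names["shared"])

    universe = sorted(
        names["planted_A"]
        + names["planted_G"]
        + names["shared"]
        + names["decoys"]
        + names["fillers_A"]
        + names["fillers_B"]
        + names["fillers_C"]
        + names["fillers_bg"]
    )
    truth = {
        "planted_A": sorted(names["planted_A"]),
        "planted_general": sorted(names["planted_G"]),
        "planted_markers": sorted(names["planted_A"] + names["planted_G"]),
        "shared": sorted(names["shared"]),
        "decoys": sorted(names["decoys"]),
        "universe": universe,
        "seed": cfg.seed,
    }
    return SyntheticBundle(
        config=cfg,
        associations=tuple(associations),
        targets=tuple(targets),
        annotations=tuple(annotations),
        ppi=tuple(ppi),
        regulation=tuple(regulation),
        disease_sets=disease_sets,
        truth=truth,
    )


def degrade_bundle(
    bundle: SyntheticBundle, drop_frac: float, seed: int
) -> SyntheticBundle:
    """Drop a fraction of target and PPI edges uniformly at random.

    The truth record is left unchanged, so planted-marker recovery on the
    degraded bundle measures robustness to missing evidence.
    """
    if not 0.0 <= drop_frac < 1.0:
        raise ConfigError(f"drop_frac must be in [0, 1), got {drop_frac}")
    if drop_frac == 0.0:
        return bundle
    rng = np.random.default_rng(seed)

    def keep(items: tuple, stream: np.random.Generator) -> tuple:
        n = len(items)
        n_drop = int(round(drop_frac * n))
        if n_drop == 0:
            return items
        dropped = set(stream.choice(n, size=n_drop, replace=False).tolist())
        return tuple(x for i, x in enumerate(items) if i not in dropped)

    return replace(
        bundle,
        targets=keep(bundle.targets, rng),
        ppi=keep(bundle.ppi, rng),
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the six tables plus truth.json; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": out / "associations.tsv",
        "targets": out / "targets.tsv",
        "annotations": out / "annotations.tsv",
        "ppi": out / "ppi.tsv",
        "regulation": out / "regulation.tsv",
        "disease_sets": out / "disease_sets.gmt",
        "truth": out / "truth.json",
    }
    io.write_association_table(bundle.associations, paths["associations"])
    io.write_target_table(bundle.targets, paths["targets"])
    io.write_annotation_table(bundle.annotations, paths["annotations"])
    io.write_ppi_table(bundle.ppi, paths["ppi"])
    io.write_regulation_table(bundle.regulation, paths["regulation"])
    io.write_gmt(
        {k: bundle.disease_sets[k] for k in sorted(bundle.disease_sets)},
        paths["disease_sets"],
    )
    with paths["truth"].open("w", encoding="utf-8", newline="\n") as handle:
        json.dump(dict(bundle.truth), handle, indent=2, sort_keys=True)
        handle.write("\n")
    return paths


def load_bundle(in_dir: str | Path) -> SyntheticBundle:
    """Reload a written bundle (config defaults are not recovered)."""
    d = Path(in_dir)
    with (d / "truth.json").open(encoding="utf-8") as handle:
        truth = json.load(handle)
    return SyntheticBundle(
        config=SyntheticConfig(seed=truth.get("seed", 0)),
        associations=tuple(io.read_association_table(d / "associations.tsv")),
        targets=tuple(io.read_target_table(d / "targets.tsv")),
        annotations=tuple(io.read_annotation_table(d / "annotations.tsv")),
        ppi=tuple(io.read_ppi_table(d / "ppi.tsv")),
        regulation=tuple(io.read_regulation_table(d / "regulation.tsv")),
        disease_sets=io.read_gmt(d / "disease_sets.gmt"),
        truth=truth,
    )
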