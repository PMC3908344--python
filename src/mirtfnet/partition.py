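"""Split miRNA-cohort associations into unique and common sets with tallies."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from mirtfnet.model import (
    CONFLICT,
    COHORTS,
    DIFFERENTIAL,
    MiRNAAssociation,
)

COHORT_A, COHORT_B = COHORTS  # NSCLC, SCLC


@dataclass(frozen=True)
class PartitionResult:
    """Cohort-unique and common miRNA sets plus direction tallies.

    ``unique_A``/``unique_B`` tallies count ``up``/``down``/``conflict``;
    the ``common`` tally additionally counts ``differential`` (opposite
    directions in the two cohorts).
    """

    unique_A: frozenset[str]
    unique_B: frozenset[str]
    common: frozenset[str]
    tallies: Mapping[str, Mapping[str, int]] = field(default_factory=dict)

    @property
    def universe(self) -> frozenset[str]:
        return self.unique_A | self.unique_B | self.common


def _direction_for_common(assoc: MiRNAAssociation) -> str:
    if assoc.is_differential():
        return DIFFERENTIAL
    directions = set(assoc.directions.values())
    if directions == {"up"}:
        return "up"
    if directions == {"down"}:
        return "down"
    return CONFLICT


def partition_mirnas(
    associations: Iterable[MiRNAAssociation],
) -> PartitionResult:
    """Partition miRNAs into cohort-unique and common sets.

    A miRNA carrying both cohort labels is common; when its two directions
    are opposite it tallies as ``differential``.  A within-cohort
    ``conflict`` direction is counted in neither the up nor the down tally.
    """
    associations = list(associations)
    if not associations:
        raise ValueError("associations must be non-empty")
    by_id: dict[str, MiRNAAssociation] = {}
    for assoc in associations:
        if not assoc.directions:
            raise ValueError(f"miRNA {assoc.mirna_id!r} has no cohorts")
        if assoc.mirna_id in by_id:
            raise ValueError(f"duplicate association for {assoc.mirna_id!r}")
        by_id[assoc.mirna_id] = assoc

    unique_a: set[str] = set()
    unique_b: set[str] = set()
    common: set[str] = set()
    tallies = {
        "unique_A": {"up": 0, "down": 0, CONFLICT: 0},
        "unique_B": {"up": 0, "down": 0, CONFLICT: 0},
        "common": {"up": 0, "down": 0, DIFFERENTIAL: 0, CONFLICT: 0},
    }
    for assoc in by_id.values():
        subtypes = assoc.subtypes
        if subtypes == {COHORT_A, COHORT_B}:
            common.add(assoc.mirna_id)
            tallies["common"][_direction_for_common(assoc)] += 1
        elif subtypes == {COHORT_A}:
            unique_a.add(assoc.mirna_id)
            d = assoc.directions[COHORT_A]
            tallies["unique_A"][d if d in ("up", "down") else CONFLICT] += 1
        else:
            unique_b.add(assoc.mirna_id)
            d = assoc.directions[COHORT_B]
            tallies["unique_B"][d if d in ("up", "down") else CONFLICT] += 1

    return PartitionResult(
        unique_A=frozenset(unique_a),
        unique_B=frozenset(unique_b),
        common=frozenset(common),
        tallies=tallies,
    )


def partition_report(result: PartitionResult) -> dict:
    """Machine-readable counts per set, cross-checked by inclusion-exclusion."""
    n_a_total = len(result.unique_A) + len(result.common)
    n_b_total = len(result.unique_B) + len(result.common)
    total = len(result.universe)
    report = {
        "unique_A": {
            "count": len(result.unique_A),
            "tallies": dict(result.tallies.get("unique_A", {})),
        },
        "unique_B": {
            "count": len(result.unique_B),
            "tallies": dict(result.tallies.get("unique_B", {})),
        },
        "common": {
            "count": len(result.common),
            "tallies": dict(result.tallies.get("common", {})),
        },
        "cohort_totals": {COHORT_A: n_a_total, COHORT_B: n_b_total},
        "total": total,
        "inclusion_exclusion_ok": (
            n_a_total + n_b_total - len(result.common) == total
        ),
    }
    return report


def write_partition_report(result: PartitionResult, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as handle:
        json.dump(partition_report(result), handle, indent=2, sort_keys=True)
        handle.write("\n")
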