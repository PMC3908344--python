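"""Packaged reference data: published marker gene groups and miRNA counts.

The gene groups ship as a GMT file inside the package; the association
fixture encodes the published cohort totals (184 NSCLC-associated and 62
SCLC-associated miRNAs, 41 associated with both) with generic miRNA ids.
"""

from __future__ import annotations

from importlib import resources

from mirtfnet.io import read_gmt
from mirtfnet.model import (
    GROUP_NAMES,
    MiRNAAssociation,
    RegulatoryNetwork,
)

#: published cohort totals used to build the association fixture
N_NSCLC_TOTAL = 184
N_SCLC_TOTAL = 62
N_BOTH = 41

#: published direction tallies; entries not covered by the printed up/down
#: counts are carried as study-level conflicts or differential calls
_NSCLC_UNIQUE_UP = 89
_NSCLC_UNIQUE_DOWN = 43
_SCLC_UNIQUE_UP = 16
_COMMON_UP = 13
_COMMON_DOWN = 11


def reference_gene_groups() -> dict[str, frozenset[str]]:
    """The six published marker gene groups, keyed by group name."""
    source = resources.files("mirtfnet.data") / "marker_gene_groups.gmt"
    with resources.as_file(source) as path:
        groups = read_gmt(path)
    missing = [name for name in GROUP_NAMES if name not in groups]
    if missing:  # packaged data is under our control; defensive only
        raise RuntimeError(f"fixture GMT missing groups: {missing}")
    return groups


def reference_networks() -> tuple[RegulatoryNetwork, RegulatoryNetwork, RegulatoryNetwork]:
    """Edge-less cohort networks reconstructed from the gene groups.

    NSCLC = groups 2 | 4 | 5, SCLC = group 1, common = groups 3 | 4 | 6.
    """
    g = reference_gene_groups()
    nsclc = g["common_SCLC_NSCLC"] | g["common_NSCLC_general"] | g["NSCLC_specific"]
    sclc = g["unique_SCLC"]
    common = g["common_all"] | g["common_NSCLC_general"] | g["general_specific"]
    return (
        RegulatoryNetwork.from_parts("NSCLC", genes=nsclc),
        RegulatoryNetwork.from_parts("SCLC", genes=sclc),
        RegulatoryNetwork.from_parts("common", genes=common),
    )


def reference_marker_panel() -> frozenset[str]:
    """The seven genes selected from the subtype-specific groups."""
    g = reference_gene_groups()
    return g["NSCLC_specific"] | g["general_specific"]


def reference_associations() -> list[MiRNAAssociation]:
    """Association fixture with the published cohort totals.

    143 miRNAs carry only the NSCLC label, 21 only SCLC, 41 both, so the
    per-cohort totals are 184 and 62.  Directions follow the published
    tallies where they are consistent with the set arithmetic; remainders
    are carried as ``conflict`` (within-cohort disagreement) or
    ``differential`` (opposite directions between cohorts).
    """
    n_nsclc_only = N_NSCLC_TOTAL - N_BOTH  # 143
    n_sclc_only = N_SCLC_TOTAL - N_BOTH  # 21
    out: list[MiRNAAssociation] = []

    for i in range(n_nsclc_only):
        if i < _NSCLC_UNIQUE_UP:
            direction = "up"
        elif i < _NSCLC_UNIQUE_UP + _NSCLC_UNIQUE_DOWN:
            direction = "down"
        else:
            direction = "conflict"
        out.append(
            MiRNAAssociation(f"mir-N{i + 1:03d}", {"NSCLC": direction})
        )
    for i in range(n_sclc_only):
        direction = "up" if i < _SCLC_UNIQUE_UP else "down"
        out.append(
            MiRNAAssociation(f"mir-S{i + 1:03d}", {"SCLC": direction})
        )
    for i in range(N_BOTH):
        if i < _COMMON_UP:
            directions = {"NSCLC": "up", "SCLC": "up"}
        elif i < _COMMON_UP + _COMMON_DOWN:
            directions = {"NSCLC": "down", "SCLC": "down"}
        else:
            directions = {"NSCLC": "up", "SCLC": "down"}
        out.append(MiRNAAssociation(f"mir-C{i + 1:03d}", directions))
    return out
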