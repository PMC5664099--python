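"""Identification criteria and 12-way domain-architecture classification.

A candidate is kept as an nTNL gene when it (1) carries an NB-ARC module
(P-loop, Kinase-2 and GLPL all present, in N→C order), (2) is not a TIR
(TNL) gene, and (3) is not a pseudogene (no stop codon before the LRR
region). LRR-less sequences are retained and labelled within the N/CN/RN/
BN families rather than rejected — the accounting used for the reference
Arabidopsis set keeps such genes.

The 12 subgroups are the product {∅, C, R, RC, B, BC} x {N, NL} over the
flags (RPW8?, BED?, CC?) and LRR: N, NL, CN, CNL, RN, RNL, RCN, RCNL, BN,
BNL, BCN, BCNL. RPW8 and BED prefixes are mutually exclusive; no class is
defined for a protein carrying both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motifscan import MotifHit

KEPT = "kept_nTNL"
REJECTED_TIR = "rejected_TIR"
REJECTED_NO_NBARC = "rejected_no_NBARC"
REJECTED_NO_LRR = "rejected_no_LRR_class_N_family"
REJECTED_MISSING_CORE_MOTIF = "rejected_missing_core_motif"
REJECTED_PSEUDOGENE = "rejected_pseudogene"

STATUSES = (
    KEPT,
    REJECTED_TIR,
    REJECTED_NO_NBARC,
    REJECTED_NO_LRR,
    REJECTED_MISSING_CORE_MOTIF,
    REJECTED_PSEUDOGENE,
)

SUBGROUP_LABELS = (
    "N", "NL", "CN", "CNL", "RN", "RNL", "RCN", "RCNL", "BN", "BNL", "BCN", "BCNL",
)

#: Kinase-2 terminal residue -> class call. The Methods convention: an
#: aspartate-terminal Kinase-2 (…DDVD) marks a non-TNL protein, tryptophan
#: (…DDVW) a TNL-type one. The opposite mapping can be passed explicitly.
DEFAULT_KINASE2_MAP: Mapping[str, str] = {"D": "nTNL_type", "W": "TNL_type"}


@dataclass
class ArchitectureCall:
    gene_id: str
    flags: dict[str, bool]
    kinase2_terminal: str | None = None
    subgroup_label: str = ""
    status: str = ""
    reasons: list[str] = field(default_factory=list)


def _flag(hits: Mapping[str, Sequence[MotifHit]], motif: str) -> bool:
    return bool(hits.get(motif))


def domain_flags(hits: Mapping[str, Sequence[MotifHit]]) -> dict[str, bool]:
    """Presence flags for the six classification domains.

    NBS means a complete NB-ARC: P-loop, Kinase-2 and GLPL all detected.
    """
    return {
        "CC": _flag(hits, "CC"),
        "NBS": _flag(hits, "PLOOP") and _flag(hits, "KINASE2") and _flag(hits, "GLPL"),
        "LRR": _flag(hits, "LRR"),
        "RPW8": _flag(hits, "RPW8"),
        "BED": _flag(hits, "BED"),
        "TIR": _flag(hits, "TIR"),
    }


def apply_identification_criteria(
    gene_id: str, hits: Mapping[str, Sequence[MotifHit]]
) -> ArchitectureCall:
    """Apply the three identification criteria; returns a status-only call.

    TIR presence rejects the gene regardless of other flags; a missing
    NB-ARC rejects it; otherwise the gene proceeds to core-motif
    verification (an empty status).
    """
    flags = domain_flags(hits)
    call = ArchitectureCall(gene_id=gene_id, flags=flags)
    if flags["TIR"]:
        call.status = REJECTED_TIR
        call.reasons.append("TIR domain present: TNL gene")
    elif not flags["NBS"]:
        call.status = REJECTED_NO_NBARC
        call.reasons.append("no complete NB-ARC (P-loop/Kinase-2/GLPL)")
    return call


def verify_core_motifs(hits: Mapping[str, Sequence[MotifHit]]) -> bool:
    """True iff P-loop, Kinase-2 and GLPL are all present in N→C order."""
    ploop, k2, glpl = hits.get("PLOOP"), hits.get("KINASE2"), hits.get("GLPL")
    if not (ploop and k2 and glpl):
        return False
    return ploop[0].start < k2[0].start < glpl[-1].start


def kinase2_rule(
    kinase2: MotifHit, mapping: Mapping[str, str] = DEFAULT_KINASE2_MAP
) -> str:
    """Classify by the Kinase-2 terminal residue (DDVD vs DDVW).

    Returns ``nTNL_type``, ``TNL_type`` or ``indeterminate``. A TNL-type
    Kinase-2 flags the gene; it does not by itself reject it.
    """
    matched = kinase2.matched
    if matched.endswith("DDVD"):
        return mapping.get("D", "indeterminate")
    if matched.endswith("DDVW"):
        return mapping.get("W", "indeterminate")
    return "indeterminate"


def classify_architecture(flags: Mapping[str, bool]) -> str:
    """The 12-way subgroup label from the domain flags; requires NBS."""
    if not flags.get("NBS"):
        raise ValueError("classify_architecture requires the NBS flag")
    if flags.get("RPW8") and flags.get("BED"):
        raise ValueError("RPW8 and BED both present: no such class is defined")
    if flags.get("RPW8"):
        prefix = "RC" if flags.get("CC") else "R"
    elif flags.get("BED"):
        prefix = "BC" if flags.get("CC") else "B"
    else:
        prefix = "C" if flags.get("CC") else ""
    return prefix + ("NL" if flags.get("LRR") else "N")


def pseudogene_filter(
    protein: str, lrr: MotifHit | None
) -> bool:
    """True (= remove) when a stop codon precedes the LRR region.

    With no LRR hit, any internal stop (i.e. not at the final position)
    marks the gene as a pseudogene.
    """
    if lrr is not None:
        return "*" in protein[: lrr.start]
    internal = protein[:-1] if protein.endswith("*") else protein
    return "*" in internal


def classify_gene(
    gene_id: str,
    protein: str,
    hits: Mapping[str, Sequence[MotifHit]],
    require_lrr: bool = False,
    kinase2_map: Mapping[str, str] = DEFAULT_KINASE2_MAP,
) -> ArchitectureCall:
    """Full per-gene classification: criteria, motif verification,
    pseudogene filter, Kinase-2 rule, subgroup label."""
    call = apply_identification_criteria(gene_id, hits)
    if call.status:
        return call
    if not verify_core_motifs(hits):
        call.status = REJECTED_MISSING_CORE_MOTIF
        call.reasons.append("core motifs absent or out of order")
        return call
    lrr = hits["LRR"][0] if hits.get("LRR") else None
    if pseudogene_filter(protein, lrr):
        call.status = REJECTED_PSEUDOGENE
        call.reasons.append("stop codon before the LRR region")
        return call
    if require_lrr and lrr is None:
        call.status = REJECTED_NO_LRR
        call.reasons.append("no LRR region (strict mode)")
        return call
    k2 = hits["KINASE2"][0]
    call.kinase2_terminal = k2.matched[-1] if k2.matched else None
    k2_class = kinase2_rule(k2, kinase2_map)
    if k2_class == "TNL_type":
        call.reasons.append("TNL-type Kinase-2 terminal residue (flag only)")
    call.subgroup_label = classify_architecture(call.flags)
    call.status = KEPT
    return call


def tabulate_by_clade(
    assignments: Iterable[tuple[str, str]] | None = None,
    counts: Mapping[tuple[str, str], int] | None = None,
    species_order: Sequence[str] | None = None,
    clade_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Clade x species contingency table with row/column totals.

    ``assignments`` is an iterable of (species, clade) pairs, one per kept
    gene; alternatively pre-summed ``counts`` keyed by (species, clade) may
    be given (e.g. from a published table). Returns clades as rows and
    species as columns, with a ``Total`` row and column; the grand total
    equals the number of kept genes.
    """
    if (assignments is None) == (counts is None):
        raise ValueError("provide exactly one of assignments or counts")
    tallies: dict[tuple[str, str], int] = {}
    if assignments is not None:
        for species, clade in assignments:
            tallies[(species, clade)] = tallies.get((species, clade), 0) + 1
    else:
        tallies = dict(counts)  # type: ignore[arg-type]
    species = list(species_order) if species_order else sorted({s for s, _ in tallies})
    clades = list(clade_order) if clade_order else sorted({c for _, c in tallies})
    unknown = {s for s, _ in tallies} - set(species)
    if unknown:
        raise ValueError(f"genes with unknown species: {sorted(unknown)}")
    table = pd.DataFrame(0, index=clades, columns=species, dtype=int)
    for (s, c), n in tallies.items():
        if c not in table.index:
            raise ValueError(f"clade {c!r} not in clade_order")
        table.loc[c, s] += n
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table
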