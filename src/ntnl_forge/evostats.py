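"""Molecular-evolution statistics: NG86 Ka/Ks, G+C content, exon structure
and expression summarisation.

Ka/Ks follows Nei & Gojobori (1986): per-codon synonymous/nonsynonymous
site fractions from the nine single-nucleotide neighbours, differences
decomposed over minimal mutational pathways with equal weighting
(pathways passing through stop codons excluded), and Jukes–Cantor
correction K = -(3/4) ln(1 - 4p/3). Ks is undefined (reported as NA)
when ps >= 3/4 or no synonymous sites exist; the ratio is undefined when
either distance is, or when Ks = 0.

Conventions that results depend on: neighbour mutations that create stop
codons count as nonsynonymous in site counting, and if every pathway
between two codons passes through a stop, all pathways are used with
stop-crossing steps counted as nonsynonymous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from Bio.Data import CodonTable

from .seqio import ExpressionMatrix

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_CODON_AA))
_BASES = "ACGT"


@dataclass
class KaKsResult:
    syn_sites: float          # S, averaged over the two sequences
    nonsyn_sites: float       # N
    syn_diffs: float          # Sd
    nonsyn_diffs: float       # Nd
    ps: float
    pn: float
    ks: float | None          # Jukes–Cantor corrected; None when undefined
    ka: float | None
    ratio: float | None       # Ka/Ks; None when undefined

    @property
    def defined(self) -> bool:
        return self.ratio is not None


@dataclass
class SubcladeKaKsSummary:
    subclade: str
    n_members: int
    n_pairs: int              # all C(n, 2) pairs
    n_defined_pairs: int
    min_ratio: float | None
    max_ratio: float | None
    avg_ratio: float | None


def _sites_for(codon: str) -> tuple[float, float]:
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            neighbor = codon[:pos] + b + codon[pos + 1 :]
            # stops count as nonsynonymous in site counting
            if neighbor not in STOP_CODONS and _CODON_AA[neighbor] == _CODON_AA[codon]:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


_SITES: dict[str, tuple[float, float]] = {c: _sites_for(c) for c in SENSE_CODONS}


def ng86_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one sense codon; sums to 3."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    if codon not in _SITES:
        raise ValueError(f"not a codon: {codon!r}")
    return _SITES[codon]


def _path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged over minimal
    mutational pathways with equal weight; stop-passing paths excluded
    (falling back to all paths if none survive)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                nonsyn += 1
            elif cur in STOP_CODONS:
                through_stop = True
                nonsyn += 1
            elif _CODON_AA[nxt] == _CODON_AA[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked if through_stop else valid).append((syn, nonsyn))
    paths = valid if valid else blocked
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


_PAIR_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _pair_diffs_cached(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    if key not in _PAIR_DIFFS:
        _PAIR_DIFFS[key] = _path_diffs(*key)
    return _PAIR_DIFFS[key]


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_pair(cds1: str, cds2: str) -> KaKsResult:
    """NG86 Ka/Ks with Jukes–Cantor correction for one aligned CDS pair.

    Sequences must be equal-length, in frame, gap-free and free of
    internal stop codons.
    """
    cds1, cds2 = cds1.upper(), cds2.upper()
    if len(cds1) != len(cds2):
        raise ValueError(f"length mismatch: {len(cds1)} vs {len(cds2)}")
    if len(cds1) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds1), 3):
        a, b = cds1[i : i + 3], cds2[i : i + 3]
        for name, codon in (("first", a), ("second", b)):
            if codon in STOP_CODONS:
                raise ValueError(f"internal stop codon in {name} sequence at nt {i}")
            if codon not in _SITES:
                raise ValueError(f"invalid codon {codon!r} at nt {i}")
        s1, n1 = _SITES[a]
        s2, n2 = _SITES[b]
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _pair_diffs_cached(a, b)
        Sd += sd
        Nd += nd
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ks = _jc(ps) if S > 0 else None
    ka = _jc(pn) if N > 0 else None
    ratio = ka / ks if (ks is not None and ks > 0 and ka is not None) else None
    return KaKsResult(S, N, Sd, Nd, ps, pn, ks, ka, ratio)


def subclade_kaks_summary(
    members: Sequence[tuple[str, str]], subclade: str
) -> SubcladeKaKsSummary:
    """Min/max/average Ka/Ks over all member pairs of one subclade.

    Pairs with an undefined ratio (identical sequences, saturated ps, or
    Ks = 0) are excluded from the statistics and counted in the report.
    """
    if len(members) < 2:
        raise ValueError("a subclade summary needs at least 2 members")
    ratios: list[float] = []
    n_pairs = 0
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            n_pairs += 1
            res = ng86_pair(members[i][1], members[j][1])
            if res.ratio is not None:
                ratios.append(res.ratio)
    if ratios:
        return SubcladeKaKsSummary(
            subclade, len(members), n_pairs, len(ratios),
            min(ratios), max(ratios), sum(ratios) / len(ratios),
        )
    return SubcladeKaKsSummary(subclade, len(members), n_pairs, 0, None, None, None)


# ---------------------------------------------------------------------------
# composition, gene structure, expression
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); ambiguity codes excluded from both terms."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / (gc + at)


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def exon_stats(
    groups: Mapping[str, Sequence[int]]
) -> dict[str, tuple[int, int, float]]:
    """Per-group (max, min, average) exon counts.

    The average is rounded half-up to 1 decimal; an empty group reports
    (0, 0, 0.0), matching the convention used for absent clades.
    """
    out: dict[str, tuple[int, int, float]] = {}
    for name, counts in groups.items():
        if not counts:
            out[name] = (0, 0, 0.0)
        else:
            out[name] = (
                max(counts),
                min(counts),
                _round_half_up(sum(counts) / len(counts), 1),
            )
    return out


def summarize_expression(
    matrix: ExpressionMatrix,
    high_quantile: float = 0.9,
    basal_quantile: float = 0.1,
) -> pd.DataFrame:
    """Replicate-averaged, log2-transformed expression with a high/basal call.

    Per condition: mean of replicates, then log2(mean + 1). Each gene's
    grand mean (across conditions) is ranked against the stated quantiles
    of all genes: strictly above the high quantile -> ``high``, strictly
    below the basal quantile -> ``basal``, otherwise ``mid`` (so a
    degenerate all-equal matrix is all ``mid``).
    """
    values = matrix.values
    unknown = [s for s in values.columns if s not in matrix.replicate_groups]
    if unknown:
        raise KeyError(f"samples missing from the replicate map: {unknown}")
    conditions = sorted(set(matrix.replicate_groups.values()))
    cols = {}
    for cond in conditions:
        samples = [s for s in values.columns if matrix.replicate_groups[s] == cond]
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
        cols[cond] = np.log2(values[samples].mean(axis=1) + 1.0)
    df = pd.DataFrame(cols)
    df["grand_mean"] = df[conditions].mean(axis=1)
    hi = float(np.quantile(df["grand_mean"], high_quantile))
    lo = float(np.quantile(df["grand_mean"], basal_quantile))
    df["category"] = "mid"
    df.loc[df["grand_mean"] > hi, "category"] = "high"
    df.loc[df["grand_mean"] < lo, "category"] = "basal"
    df.index.name = "gene_id"
    return df
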