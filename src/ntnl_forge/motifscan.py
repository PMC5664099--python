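"""Locate NB-ARC core motifs and accessory domains on proteins.

Two layers of detection are provided:

* **Fixed-pattern detectors** for the short conserved words of the NB-ARC
  module (P-loop, Kinase-2, GLPL) and the accessory domains (TIR, RPW8,
  BED zinc finger), plus structural detectors for LRR repeats (LxxLxxLxx
  frames) and coiled-coil heptads.

* **A gapless log-odds profile (PSSM)** built from a seed multiple
  alignment, scanned against whole proteomes with empirical e-values from
  within-sequence shuffles. The two-pass search retains hits at e < 0.05
  against the seed profile, rebuilds a genome-specific profile from the
  retained best-hit windows, and rescans the proteome at e < 0.001 —
  mirroring iterative homolog retrieval with a genome-specific model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
HYDROPHOBIC = frozenset("LIVM")
GAP_CHARS = frozenset("-.")

#: Fixed patterns; lowercase ``x`` marks a wildcard position (any residue).
#: Kinase-2's terminal residue is a wildcard because its identity (D vs W)
#: is read downstream as a classification signal, not a detection criterion.
PATTERNS: dict[str, str] = {
    "PLOOP": "GGVGKTT",
    "KINASE2": "LLVLDDVx",
    "GLPL": "GLPLAL",
    "TIR": "FDAFISHA",
    "RPW8": "WEALVKEV",
    "BED": "CxxCxxxxxxxxxxCxxH",
}

STRUCTURAL_MOTIFS = ("LRR", "CC")
SUPPORTED_MOTIFS = tuple(PATTERNS) + STRUCTURAL_MOTIFS + ("NBARC",)

DEFAULT_MAX_MISMATCHES = 2
LRR_MIN_FRAMES = 3       # >= 3 consecutive LxxLxxLxx frames
CC_MIN_HEPTADS = 4       # >= 4 heptads with hydrophobic a/d positions


@dataclass(frozen=True)
class MotifHit:
    """A located motif on a protein; 0-based half-open coordinates."""

    motif: str
    start: int
    end: int
    score: float
    matched: str


@dataclass
class ProfileModel:
    """Gapless position-specific scoring matrix in bits.

    ``log_odds[j, a]`` is log2 of the pseudocounted column frequency of
    residue ``a`` over its background frequency.
    """

    log_odds: np.ndarray          # shape (length, 20)
    background: np.ndarray        # shape (20,), sums to 1
    pseudocount: float

    @property
    def length(self) -> int:
        return self.log_odds.shape[0]

    def extended_matrix(self) -> np.ndarray:
        """Log-odds with a 21st zero column for non-standard residues."""
        return np.hstack([self.log_odds, np.zeros((self.length, 1))])


@dataclass(frozen=True)
class ScanHit:
    """Best gapless profile hit on one sequence with its empirical e-value."""

    sequence_id: str
    best_offset: int | None
    bit_score: float
    evalue: float


# ---------------------------------------------------------------------------
# fixed-pattern and structural detectors
# ---------------------------------------------------------------------------

def _pattern_hits(protein: str, motif: str, max_mismatches: int) -> list[MotifHit]:
    pattern = PATTERNS[motif]
    plen = len(pattern)
    fixed = [(j, c) for j, c in enumerate(pattern) if c != "x"]
    hits: list[MotifHit] = []
    last_end = -1
    for s in range(len(protein) - plen + 1):
        if s < last_end:  # merge overlapping candidates into the leftmost
            continue
        mm = sum(1 for j, c in fixed if protein[s + j] != c)
        if mm <= max_mismatches:
            hits.append(
                MotifHit(motif, s, s + plen, float(len(fixed) - mm), protein[s : s + plen])
            )
            last_end = s + plen
    return hits


def _lrr_hits(protein: str) -> list[MotifHit]:
    """Maximal runs of 3-periodic leucines, reported as whole LxxLxxLxx frames."""
    hits: list[MotifHit] = []
    n = len(protein)
    s = 0
    while s < n:
        if protein[s] != "L" or (s >= 3 and protein[s - 3] == "L"):
            s += 1
            continue
        run = 0
        while s + 3 * run < n and protein[s + 3 * run] == "L":
            run += 1
        frames = run // 3
        if frames >= LRR_MIN_FRAMES:
            end = s + 9 * frames
            hits.append(MotifHit("LRR", s, end, float(frames), protein[s:end]))
            s = s + 3 * run
        else:
            s += 1
    return hits


def _cc_hits(protein: str) -> list[MotifHit]:
    """Maximal heptad runs with hydrophobic residues at the a and d positions."""
    hits: list[MotifHit] = []
    n = len(protein)
    s = 0
    while s < n:
        h = 0
        while (
            s + 7 * h + 3 < n + 1
            and s + 7 * (h + 1) <= n
            and protein[s + 7 * h] in HYDROPHOBIC
            and protein[s + 7 * h + 3] in HYDROPHOBIC
        ):
            h += 1
        if h >= CC_MIN_HEPTADS:
            end = s + 7 * h
            hits.append(MotifHit("CC", s, end, float(h), protein[s:end]))
            s = end
        else:
            s += 1
    return hits


def find_motif(
    protein: str, motif: str, max_mismatches: int = DEFAULT_MAX_MISMATCHES
) -> list[MotifHit]:
    """Locate all non-overlapping occurrences of one motif, sorted by start.

    Fixed-pattern motifs tolerate up to ``max_mismatches`` substitutions at
    non-wildcard positions; overlapping candidates are merged into the
    leftmost. ``NBARC`` is a derived motif: present when P-loop, Kinase-2
    and GLPL all occur in N→C order, spanning P-loop start to GLPL end.
    """
    if motif not in SUPPORTED_MOTIFS:
        raise ValueError(f"unknown motif {motif!r}; supported: {SUPPORTED_MOTIFS}")
    if motif == "LRR":
        return _lrr_hits(protein)
    if motif == "CC":
        return _cc_hits(protein)
    if motif == "NBARC":
        return _nbarc_hits(protein, max_mismatches)
    return _pattern_hits(protein, motif, max_mismatches)


def _nbarc_hits(protein: str, max_mismatches: int) -> list[MotifHit]:
    ploop = _pattern_hits(protein, "PLOOP", max_mismatches)
    k2 = _pattern_hits(protein, "KINASE2", max_mismatches)
    glpl = _pattern_hits(protein, "GLPL", max_mismatches)
    if not (ploop and k2 and glpl):
        return []
    p, k, g = ploop[0], k2[0], glpl[-1]
    if not (p.start < k.start < g.start):
        return []
    return [MotifHit("NBARC", p.start, g.end, p.score + k.score + g.score,
                     protein[p.start : g.end])]


def scan_architecture(
    protein: str, max_mismatches: int = DEFAULT_MAX_MISMATCHES
) -> dict[str, list[MotifHit]]:
    """Run every detector on one protein; keys are motif names."""
    return {m: find_motif(protein, m, max_mismatches) for m in SUPPORTED_MOTIFS}


def extract_nbarc(protein: str, ploop: MotifHit, glpl: MotifHit, pad: int = 20) -> str:
    """Trim the NB-ARC segment: ``pad`` residues before the P-loop through
    ``pad`` residues after the GLPL, clamped to the protein ends."""
    if ploop.start >= glpl.end:
        raise ValueError(
            f"GLPL (end {glpl.end}) does not follow the P-loop (start {ploop.start})"
        )
    return protein[max(0, ploop.start - pad) : min(len(protein), glpl.end + pad)]


# ---------------------------------------------------------------------------
# profile construction and scanning
# ---------------------------------------------------------------------------

def build_profile(
    alignment: Sequence[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileModel:
    """Build a gapless log-odds profile from a (possibly gapped) alignment.

    Columns with >= 50% gaps are dropped. The per-column score for residue
    ``a`` is ``log2(((count_a + pc) / (n + 20 pc)) / bg_a)`` where ``n`` is
    the number of non-gap residues in the column.
    """
    if not alignment:
        raise ValueError("empty alignment")
    if len(alignment) < 2:
        raise ValueError("need at least 2 aligned sequences")
    width = len(alignment[0])
    if any(len(s) != width for s in alignment):
        raise ValueError("aligned sequences must have equal length")
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not math.isclose(background.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("background must be 20 frequencies summing to 1")

    columns = []
    for j in range(width):
        col = [s[j] for s in alignment]
        # non-standard residues (e.g. '*') are treated as gaps
        gaps = sum(1 for c in col if c not in AA_INDEX)
        if gaps / len(col) >= 0.5:
            continue
        counts = np.zeros(20)
        n = 0
        for c in col:
            if c not in AA_INDEX:
                continue
            counts[AA_INDEX[c]] += 1
            n += 1
        freqs = (counts + pseudocount) / (n + 20 * pseudocount)
        columns.append(np.log2(freqs / background))
    if not columns:
        raise ValueError("no columns with < 50% gaps")
    return ProfileModel(np.array(columns), background, pseudocount)


def _encode(protein: str) -> np.ndarray:
    """Residues to indices 0..19; anything else (e.g. '*') to 20 (zero score)."""
    return np.array([AA_INDEX.get(c, 20) for c in protein], dtype=np.intp)


def _window_scores(matrix: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Summed column scores at every gapless offset (1-D over offsets)."""
    L = matrix.shape[0]
    n_off = encoded.size - L + 1
    scores = np.zeros(n_off)
    for j in range(L):
        scores += matrix[j, encoded[j : j + n_off]]
    return scores


def scan_profile(
    profile: ProfileModel,
    protein: str,
    n_decoys: int = 100,
    seed: int = 0,
    database_size: int = 1,
    sequence_id: str = "",
) -> ScanHit:
    """Best gapless profile hit with an empirical shuffle-based e-value.

    The bit score is the maximum over all offsets of the summed column
    scores (leftmost argmax on ties). The e-value is the fraction of
    within-sequence shuffles whose own maximum reaches the observed score,
    scaled by ``database_size``. A protein shorter than the profile yields
    a no-hit result with e-value +inf.
    """
    enc = _encode(protein)
    L = profile.length
    if enc.size < L:
        return ScanHit(sequence_id, None, float("-inf"), float("inf"))
    matrix = profile.extended_matrix()
    scores = _window_scores(matrix, enc)
    best_offset = int(np.argmax(scores))
    bit_score = float(scores[best_offset])

    if n_decoys <= 0:
        return ScanHit(sequence_id, best_offset, bit_score, float("nan"))
    rng = np.random.default_rng(seed)
    # batch of within-sequence shuffles: random keys -> argsort permutations
    order = np.argsort(rng.random((n_decoys, enc.size)), axis=1)
    decoys = enc[order]
    n_off = enc.size - L + 1
    dscores = np.zeros((n_decoys, n_off))
    for j in range(L):
        dscores += matrix[j, decoys[:, j : j + n_off]]
    k = int(np.sum(dscores.max(axis=1) >= bit_score))
    evalue = k / n_decoys * database_size
    return ScanHit(sequence_id, best_offset, bit_score, evalue)


def two_pass_search(
    seed_profile: ProfileModel,
    proteome: Mapping[str, str],
    e1: float = 0.05,
    e2: float = 0.001,
    n_decoys: int = 200,
    seed: int = 0,
    pseudocount: float = 1.0,
    verify_nbarc: bool = True,
) -> tuple[set[str], ProfileModel | None]:
    """Two-threshold iterative profile search over a proteome.

    Pass 1 retains sequences with e-value < ``e1`` against the seed
    profile; retained sequences are domain-verified (complete NB-ARC per
    the in-repo detectors, unless ``verify_nbarc`` is off) and their
    best-hit windows stacked (ungapped, anchored at the best offset) into
    a genome-specific profile. Pass 2 rescans the full proteome against
    it and retains e-value < ``e2``. The database size in each pass's
    e-value is the number of proteins scanned.

    The verification between the passes keeps a chance statistical hit
    without a real NB-ARC from contaminating — and then being reinforced
    by — the genome-specific profile.
    """
    if e2 > e1:
        raise ValueError(f"e2 ({e2}) must not exceed e1 ({e1})")
    ids = sorted(proteome)
    if not ids:
        return set(), None
    db = len(ids)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * db)]

    pass1: dict[str, ScanHit] = {}
    for i, sid in enumerate(ids):
        hit = scan_profile(
            seed_profile, proteome[sid], n_decoys, seeds[i], database_size=db,
            sequence_id=sid,
        )
        if hit.best_offset is not None and hit.evalue < e1:
            pass1[sid] = hit
    if not pass1:
        logger.warning("two_pass_search: first pass retained nothing; "
                       "no genome-specific profile built")
        return set(), None

    if verify_nbarc:
        verified = {sid: h for sid, h in pass1.items()
                    if _nbarc_hits(proteome[sid], DEFAULT_MAX_MISMATCHES)}
        dropped = set(pass1) - set(verified)
        if dropped:
            logger.info("two_pass_search: %d pass-1 hits lacked a verified "
                        "NB-ARC and were excluded from the profile rebuild", len(dropped))
        if verified:
            pass1 = verified

    L = seed_profile.length
    windows = [proteome[sid][h.best_offset : h.best_offset + L] for sid, h in pass1.items()]
    windows = [w for w in windows if len(w) == L]
    if len(windows) < 2:
        windows = windows * 2  # a single retained window still defines a profile
    profile2 = build_profile(windows, pseudocount, seed_profile.background)

    retained: set[str] = set()
    for i, sid in enumerate(ids):
        hit = scan_profile(
            profile2, proteome[sid], n_decoys, seeds[db + i], database_size=db,
            sequence_id=sid,
        )
        if hit.best_offset is not None and hit.evalue < e2:
            retained.add(sid)
    return retained, profile2
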