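"""Deterministic synthetic genomes with planted NLR domain architectures.

The generator emits a complete desk-scale test bed for every downstream
stage: a multi-chromosome genome FASTA, GFF3 gene models (gene/mRNA/exon/
CDS), protein and CDS FASTA, a truth table recording each gene's planted
architecture and motif coordinates, and a replicate-structured expression
matrix. Identical spec + seed gives byte-identical outputs.

Planted motif words (P-loop ``GGVGKTT``, Kinase-2 ``LLVLDDVD``/``...W``,
GLPL ``GLPLAL``, LRR ``LAALAALAA`` repeats, coiled-coil ``LAALAAA``
heptads, TIR ``FDAFISHA``, RPW8 ``WEALVKEV``, BED ``CxxC...CxxH``) are the
consensus sequences that this package's own detectors recognise, so the
truth table is exact by construction. Filler residues between and around
motifs are drawn from an alphabet chosen so that no window of filler can
ever reach a detector's match threshold — background false positives are
structurally impossible, not merely unlikely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from . import motifscan, seqio
from .seqio import ExpressionMatrix, GeneModel

# ---------------------------------------------------------------------------
# planted motif realisations
# ---------------------------------------------------------------------------

PLOOP = "GGVGKTT"
KINASE2_D = "LLVLDDVD"
KINASE2_W = "LLVLDDVW"
GLPL = "GLPLAL"
TIR = "FDAFISHA"
RPW8 = "WEALVKEV"
LRR_UNIT = "LAALAALAA"       # one LxxLxxLxx frame
CC_HEPTAD = "LAALAAA"        # hydrophobic a/d positions
BED = "CAAC" + "A" * 10 + "CAAH"

#: Filler alphabet. Excludes L/I/V/M/C/F/T so that, for every fixed-pattern
#: detector, the number of pattern positions a filler window could ever
#: match stays strictly below the (pattern length - mismatch tolerance)
#: acceptance threshold, and the LRR/CC structural detectors can never fire.
SAFE_AA = "ADEGHKNPQRSWY"

DOMAINS = ("CC", "NBS", "LRR", "RPW8", "BED", "TIR")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in _STANDARD.forward_table.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
_CODONS_FOR["*"] = sorted(_STANDARD.stop_codons)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()

_GC_COUNT = {c: sum(1 for b in c if b in "GC") for aas in _CODONS_FOR.values() for c in aas}


# ---------------------------------------------------------------------------
# spec types
# ---------------------------------------------------------------------------

@dataclass
class GenePlan:
    """Blueprint for one synthetic gene."""

    gene_id: str
    chromosome: str
    start: int                       # 1-based genomic start
    strand: str = "+"
    architecture: frozenset[str] = frozenset({"CC", "NBS", "LRR"})
    kinase2_terminal: str = "D"      # ignored unless NBS in architecture
    n_exons: int = 1
    premature_stop_before_lrr: bool = False
    gc_bias: float | None = None     # None -> spec.background_gc

    def __post_init__(self) -> None:
        self.architecture = frozenset(self.architecture)
        unknown = self.architecture - set(DOMAINS)
        if unknown:
            raise ValueError(f"{self.gene_id}: unknown domains {sorted(unknown)}")
        if self.n_exons < 1:
            raise ValueError(f"{self.gene_id}: n_exons must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.kinase2_terminal not in ("D", "W"):
            raise ValueError(f"{self.gene_id}: kinase2_terminal must be D or W")


@dataclass
class ExpressionPlan:
    n_conditions: int = 4
    n_replicates: int = 3
    high_gene_ids: tuple[str, ...] = ()
    noise_sd: float = 0.3


@dataclass
class SyntheticSpec:
    seed: int
    chromosomes: list[tuple[str, int]]
    gene_plan: list[GenePlan]
    background_gc: float = 0.4
    expression_plan: ExpressionPlan = field(default_factory=ExpressionPlan)

    def __post_init__(self) -> None:
        if not (0.0 <= self.background_gc <= 1.0):
            raise ValueError("background_gc must be in [0, 1]")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")


@dataclass
class TruthRow:
    gene_id: str
    architecture: frozenset[str]
    expected_subgroup_label: str
    expected_keep: bool
    planted_motif_coordinates: list[tuple[str, int, int]]  # protein coords, 0-based half-open


@dataclass
class Bundle:
    """In-memory result of a simulation run."""

    spec: SyntheticSpec
    chromosomes: dict[str, str]
    genes: list[GeneModel]
    proteins: dict[str, str]
    cds: dict[str, str]
    truth: list[TruthRow]
    expression: ExpressionMatrix

    def truth_by_id(self) -> dict[str, TruthRow]:
        return {t.gene_id: t for t in self.truth}

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            coords = ";".join(f"{m}:{s}-{e}" for m, s, e in t.planted_motif_coordinates)
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "architecture": "+".join(sorted(t.architecture)),
                    "expected_subgroup": t.expected_subgroup_label,
                    "expected_keep": t.expected_keep,
                    "planted_motifs": coords,
                }
            )
        return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "proteins": outdir / "proteins.fasta",
            "cds": outdir / "cds.fasta",
            "gff3": outdir / "genes.gff3",
            "truth": outdir / "truth.tsv",
            "expression": outdir / "expression.tsv",
            "groups": outdir / "groups.tsv",
        }
        seqio.write_fasta(self.chromosomes, paths["genome"])
        seqio.write_fasta(dict(sorted(self.proteins.items())), paths["proteins"])
        seqio.write_fasta(dict(sorted(self.cds.items())), paths["cds"])
        write_gff3(self.genes, paths["gff3"])
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False, lineterminator="\n")
        seqio.write_expression(self.expression, paths["expression"], paths["groups"])
        return paths


# ---------------------------------------------------------------------------
# sequence-level primitives
# ---------------------------------------------------------------------------

def plant_motif(protein: str, motif_consensus: str, position: int) -> str:
    """Overwrite ``protein[position:position+len(consensus)]`` with the consensus."""
    if position < 0 or position + len(motif_consensus) > len(protein):
        raise ValueError(
            f"motif of length {len(motif_consensus)} at {position} exceeds "
            f"protein length {len(protein)}"
        )
    return protein[:position] + motif_consensus + protein[position + len(motif_consensus):]


def reverse_translate(protein: str, gc_bias: float, seed: int) -> str:
    """Encode a protein as a CDS whose G+C composition tracks ``gc_bias``.

    Synonymous codons are first drawn with binomial weights favouring the
    target composition, then individual positions are greedily switched to
    synonyms until the total G+C count is as close to the target as the
    amino-acid sequence allows. Deterministic under ``seed``; the stop
    character ``*`` is encoded as a stop codon (used for planted
    pseudogenes).
    """
    if not protein:
        return ""
    rng = np.random.default_rng(seed)
    codons: list[str] = []
    for aa in protein:
        if aa not in _CODONS_FOR:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        options = _CODONS_FOR[aa]
        w = np.array(
            [gc_bias ** _GC_COUNT[c] * (1 - gc_bias) ** (3 - _GC_COUNT[c]) for c in options]
        )
        if w.sum() == 0:
            w = np.ones(len(options))
        codons.append(options[rng.choice(len(options), p=w / w.sum())])

    target = gc_bias * 3 * len(protein)
    current = sum(_GC_COUNT[c] for c in codons)
    order = rng.permutation(len(codons))
    improved = True
    while improved and abs(current - target) > 0.5:
        improved = False
        for i in order:
            options = _CODONS_FOR[protein[i]]
            best, best_dev = codons[i], abs(current - target)
            g0 = _GC_COUNT[codons[i]]
            for c in options:
                dev = abs(current - g0 + _GC_COUNT[c] - target)
                if dev < best_dev:
                    best, best_dev = c, dev
            if best != codons[i]:
                current += _GC_COUNT[best] - g0
                codons[i] = best
                improved = True
    return "".join(codons)


def random_nt(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=length, p=p)])


def _filler(rng: np.random.Generator, n: int) -> str:
    return "".join(SAFE_AA[i] for i in rng.integers(0, len(SAFE_AA), n))


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _build_protein(
    plan: GenePlan, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int, int]]]:
    """Assemble the planted protein N→C: TIR/RPW8/BED/CC, NB-ARC, LRR."""
    arch = plan.architecture
    if "RPW8" in arch and "BED" in arch:
        raise ValueError(f"{plan.gene_id}: RPW8 and BED are mutually exclusive")
    parts: list[str] = []
    coords: list[tuple[str, int, int]] = []
    pos = 0

    def add_filler(lo: int = 6, hi: int = 12) -> None:
        nonlocal pos
        n = int(rng.integers(lo, hi + 1))
        parts.append(_filler(rng, n))
        pos += n

    def add_motif(name: str, text: str) -> None:
        nonlocal pos
        parts.append(text)
        coords.append((name, pos, pos + len(text)))
        pos += len(text)

    add_filler(8, 14)
    if "TIR" in arch:
        add_motif("TIR", TIR)
        add_filler()
    if "RPW8" in arch:
        add_motif("RPW8", RPW8)
        add_filler()
    if "BED" in arch:
        add_motif("BED", BED)
        add_filler()
    if "CC" in arch:
        add_motif("CC", CC_HEPTAD * motifscan.CC_MIN_HEPTADS)
        add_filler()
    if "NBS" in arch:
        add_motif("PLOOP", PLOOP)
        parts.append(_filler(rng, 12)); pos += 12
        add_motif("KINASE2", KINASE2_W if plan.kinase2_terminal == "W" else KINASE2_D)
        parts.append(_filler(rng, 12)); pos += 12
        add_motif("GLPL", GLPL)
    if "LRR" in arch or plan.premature_stop_before_lrr:
        add_filler(8, 12)
    if plan.premature_stop_before_lrr:
        parts.append("*")
        pos += 1
        add_filler(4, 8)
    if "LRR" in arch:
        add_motif("LRR", LRR_UNIT * 4)
    add_filler(8, 14)
    return "".join(parts), coords


def _split_exons(cds_len: int, n_exons: int, rng: np.random.Generator) -> list[int]:
    """Partition a CDS into exon lengths (each >= 6 bp when feasible)."""
    if n_exons == 1 or cds_len < 6 * n_exons:
        return [cds_len] if n_exons == 1 else [cds_len - 6 * (n_exons - 1)] + [6] * (n_exons - 1)
    cuts = sorted(rng.choice(np.arange(6, cds_len - 5), size=n_exons - 1, replace=False))
    while len(set(cuts)) != len(cuts) or any(b - a < 6 for a, b in zip(cuts, cuts[1:])):
        cuts = sorted(rng.choice(np.arange(6, cds_len - 5), size=n_exons - 1, replace=False))
    bounds = [0] + list(cuts) + [cds_len]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def _expected_subgroup(arch: frozenset[str]) -> str:
    if "NBS" not in arch or "TIR" in arch:
        return ""
    if "RPW8" in arch:
        prefix = "RC" if "CC" in arch else "R"
    elif "BED" in arch:
        prefix = "BC" if "CC" in arch else "B"
    else:
        prefix = "C" if "CC" in arch else ""
    return prefix + ("NL" if "LRR" in arch else "N")


def generate_genome(spec: SyntheticSpec) -> Bundle:
    """Generate the full bundle for one spec; deterministic under its seed."""
    rng = np.random.default_rng(spec.seed)
    chrom_lengths = dict(spec.chromosomes)
    unknown = [p.gene_id for p in spec.gene_plan if p.chromosome not in chrom_lengths]
    if unknown:
        raise ValueError(f"gene plans on unknown chromosomes: {unknown}")

    chrom_seqs = {
        name: np.frombuffer(
            random_nt(rng, length, spec.background_gc).encode(), dtype="S1"
        ).copy()
        for name, length in spec.chromosomes
    }

    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    truth: list[TruthRow] = []
    occupied: dict[str, list[tuple[int, int, str]]] = {name: [] for name in chrom_lengths}

    for plan in spec.gene_plan:
        protein, coords = _build_protein(plan, rng)
        gc = spec.background_gc if plan.gc_bias is None else plan.gc_bias
        cds = reverse_translate(protein, gc, int(rng.integers(0, 2**31)))
        exon_lens = _split_exons(len(cds), plan.n_exons, rng)

        pieces: list[str] = []
        rel_exons: list[tuple[int, int]] = []  # transcript order, 0-based half-open
        off_cds, off_gene = 0, 0
        for i, elen in enumerate(exon_lens):
            rel_exons.append((off_gene, off_gene + elen))
            pieces.append(cds[off_cds : off_cds + elen])
            off_cds += elen
            off_gene += elen
            if i < len(exon_lens) - 1:
                intron = random_nt(rng, int(rng.integers(60, 201)), spec.background_gc)
                pieces.append(intron)
                off_gene += len(intron)
        gene_seq = "".join(pieces)
        glen = len(gene_seq)
        if plan.strand == "-":
            gene_seq = seqio.reverse_complement(gene_seq)
            rel_exons = [(glen - e, glen - s) for s, e in rel_exons]
        rel_exons.sort()

        start, end = plan.start, plan.start + glen - 1
        if start < 1 or end > chrom_lengths[plan.chromosome]:
            raise ValueError(
                f"{plan.gene_id}: span {start}-{end} exceeds {plan.chromosome} "
                f"(length {chrom_lengths[plan.chromosome]})"
            )
        for s0, e0, other in occupied[plan.chromosome]:
            if start <= e0 and s0 <= end:
                raise ValueError(
                    f"coordinate conflict on {plan.chromosome}: "
                    f"{plan.gene_id} ({start}-{end}) overlaps {other} ({s0}-{e0})"
                )
        occupied[plan.chromosome].append((start, end, plan.gene_id))
        arr = chrom_seqs[plan.chromosome]
        arr[start - 1 : end] = np.frombuffer(gene_seq.encode(), dtype="S1")

        exons = [(start + s, start + e - 1) for s, e in rel_exons]
        genes.append(
            GeneModel(
                gene_id=plan.gene_id,
                chromosome=plan.chromosome,
                start=start,
                end=end,
                strand=plan.strand,
                exons=exons,
                cds=cds,
                protein=protein,
            )
        )
        proteins[plan.gene_id] = protein
        cds_map[plan.gene_id] = cds
        keep = (
            "NBS" in plan.architecture
            and "TIR" not in plan.architecture
            and not plan.premature_stop_before_lrr
        )
        truth.append(
            TruthRow(
                gene_id=plan.gene_id,
                architecture=plan.architecture,
                expected_subgroup_label=_expected_subgroup(plan.architecture),
                expected_keep=keep,
                planted_motif_coordinates=coords,
            )
        )

    expression = _generate_expression(spec, [p.gene_id for p in spec.gene_plan])
    return Bundle(
        spec=spec,
        chromosomes={name: arr.tobytes().decode() for name, arr in chrom_seqs.items()},
        genes=genes,
        proteins=proteins,
        cds=cds_map,
        truth=truth,
        expression=expression,
    )


def _generate_expression(spec: SyntheticSpec, gene_ids: Sequence[str]) -> ExpressionMatrix:
    """Lognormal baseline; planted 'high' genes shifted +3 log2 units;
    replicate noise N(0, noise_sd) on the log2 scale.

    The between-gene baseline spread (sd 0.5 log2 units) is modest
    relative to the +3 planted shift, so 'highly expressed' is a clear
    induction signal rather than the tail of the baseline distribution.
    """
    ep = spec.expression_plan
    rng = np.random.default_rng(spec.seed + 1)
    high = set(ep.high_gene_ids)
    base = rng.normal(5.0, 0.5, size=len(gene_ids))
    samples = [
        f"cond{c + 1}_rep{r + 1}"
        for c in range(ep.n_conditions)
        for r in range(ep.n_replicates)
    ]
    log2 = (
        base[:, None]
        + np.array([3.0 if g in high else 0.0 for g in gene_ids])[:, None]
        + rng.normal(0.0, ep.noise_sd, size=(len(gene_ids), len(samples)))
    )
    values = pd.DataFrame(np.power(2.0, log2), index=list(gene_ids), columns=samples)
    groups = {s: s.split("_")[0] for s in samples}
    return ExpressionMatrix(values=values, replicate_groups=groups)


# ---------------------------------------------------------------------------
# GFF3 writing
# ---------------------------------------------------------------------------

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features (one mRNA per gene, CDS == exons)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            base = f"{g.chromosome}\tntnl-forge\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(f"{base}gene\t{g.start}\t{g.end}{tail}.\tID={g.gene_id}\n")
            mid = f"{g.gene_id}.1"
            fh.write(f"{base}mRNA\t{g.start}\t{g.end}{tail}.\tID={mid};Parent={g.gene_id}\n")
            ordered = g.exons if g.strand == "+" else list(reversed(g.exons))
            phase = 0
            phases = {}
            for s, e in ordered:
                phases[(s, e)] = phase
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{base}exon\t{s}\t{e}{tail}.\tID={mid}.exon{i};Parent={mid}\n")
                fh.write(f"{base}CDS\t{s}\t{e}{tail}{phases[(s, e)]}\tID={mid}.cds;Parent={mid}\n")


# ---------------------------------------------------------------------------
# seed alignments and evolutionary simulation helpers
# ---------------------------------------------------------------------------

def make_seed_alignment(n: int = 8, seed: int = 0) -> list[str]:
    """Ungapped alignment of NB-ARC core regions (P-loop .. GLPL).

    Motif columns are invariant across sequences; the linker columns vary,
    mimicking a family alignment in which only the functional words are
    conserved.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(PLOOP + _filler(rng, 12) + KINASE2_D + _filler(rng, 12) + GLPL)
    return out


def mutate_cds_family(
    ancestor_cds: str,
    n_members: int,
    n_attempts: int = 60,
    syn_accept: float = 1.0,
    nonsyn_accept: float = 0.2,
    seed: int = 0,
) -> list[str]:
    """Evolve a family of CDS from one ancestor under tunable selection.

    Each member accumulates random single-nucleotide changes; synonymous
    proposals are accepted with probability ``syn_accept`` and
    nonsynonymous ones with ``nonsyn_accept`` (mutations creating stop
    codons are always discarded). ``nonsyn_accept < syn_accept`` emulates
    purifying selection, the reverse diversifying selection.
    """
    from .seqio import translate

    rng = np.random.default_rng(seed)
    members = []
    bases = "ACGT"
    for _ in range(n_members):
        seq = list(ancestor_cds)
        for _ in range(n_attempts):
            i = int(rng.integers(0, len(seq)))
            b = bases[rng.integers(0, 4)]
            if b == seq[i]:
                continue
            old = seq[i]
            codon_start = (i // 3) * 3
            before = "".join(seq[codon_start : codon_start + 3])
            seq[i] = b
            after = "".join(seq[codon_start : codon_start + 3])
            aa_before, aa_after = translate(before), translate(after)
            if aa_after == "*":
                seq[i] = old
                continue
            p = syn_accept if aa_before == aa_after else nonsyn_accept
            if rng.random() >= p:
                seq[i] = old
        members.append("".join(seq))
    return members


# ---------------------------------------------------------------------------
# the default study bed: 60 genes, all 12 subgroups, planted clusters
# ---------------------------------------------------------------------------

#: the 12 architecture subgroups as (label, domain set)
SUBGROUP_ARCHETYPES: list[tuple[str, frozenset[str]]] = [
    ("N", frozenset({"NBS"})),
    ("NL", frozenset({"NBS", "LRR"})),
    ("CN", frozenset({"CC", "NBS"})),
    ("CNL", frozenset({"CC", "NBS", "LRR"})),
    ("RN", frozenset({"RPW8", "NBS"})),
    ("RNL", frozenset({"RPW8", "NBS", "LRR"})),
    ("RCN", frozenset({"RPW8", "CC", "NBS"})),
    ("RCNL", frozenset({"RPW8", "CC", "NBS", "LRR"})),
    ("BN", frozenset({"BED", "NBS"})),
    ("BNL", frozenset({"BED", "NBS", "LRR"})),
    ("BCN", frozenset({"BED", "CC", "NBS"})),
    ("BCNL", frozenset({"BED", "CC", "NBS", "LRR"})),
]


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The default 60-gene study bed.

    50 keepers cover every one of the 12 subgroups (each at least four
    times for the product classes); 10 planted non-nTNL genes comprise 4
    TIR-carrying genes, 3 pseudogenes with a stop before the LRR, and 3
    genes without an NB-ARC. Genes are laid out on four chromosomes in
    runs whose start-to-start gaps alternate 70 kb (within clusters) and
    250 kb (between), so the 200-kb rule has known planted clusters; a
    fifth chromosome carries no genes at all.
    """
    chromosomes = [
        ("chr1", 3_000_000),
        ("chr2", 2_500_000),
        ("chr3", 2_000_000),
        ("chr4", 1_500_000),
        ("chr5", 400_000),
    ]
    counts = {"chr1": 18, "chr2": 16, "chr3": 14, "chr4": 12}
    gap_cycle = [70_000, 70_000, 70_000, 250_000]

    # keeper architectures: each subgroup 4x, plus two extra CNL = 50
    keeper_archs = [a for a in SUBGROUP_ARCHETYPES for _ in range(4)]
    keeper_archs += [("CNL", frozenset({"CC", "NBS", "LRR"}))] * 2
    rejects: list[tuple[str, frozenset[str], bool]] = [
        ("TIR", frozenset({"TIR", "NBS", "LRR"}), False),
        ("TIR", frozenset({"TIR", "NBS", "LRR"}), False),
        ("TIR", frozenset({"TIR", "CC", "NBS", "LRR"}), False),
        ("TIR", frozenset({"TIR", "NBS"}), False),
        ("PSEUDO", frozenset({"CC", "NBS", "LRR"}), True),
        ("PSEUDO", frozenset({"CC", "NBS", "LRR"}), True),
        ("PSEUDO", frozenset({"NBS", "LRR"}), True),
        ("BG", frozenset({"CC", "LRR"}), False),
        ("BG", frozenset({"LRR"}), False),
        ("BG", frozenset(), False),
    ]
    reject_positions = {5, 11, 17, 23, 29, 35, 41, 47, 53, 59}

    plans: list[GenePlan] = []
    exon_cycle = [1, 2, 3, 5, 7, 4, 1, 2, 6, 3]
    gidx = 0
    ki = 0  # keeper cursor
    ri = 0  # reject cursor
    for chrom in ("chr1", "chr2", "chr3", "chr4"):
        pos = 50_000
        for j in range(counts[chrom]):
            if gidx in reject_positions:
                _, arch, pseudo = rejects[ri]
                ri += 1
            else:
                _, arch = keeper_archs[ki]
                pseudo = False
                ki += 1
            plans.append(
                GenePlan(
                    gene_id=f"G{gidx:03d}",
                    chromosome=chrom,
                    start=pos,
                    strand="-" if gidx % 3 == 2 else "+",
                    architecture=arch,
                    kinase2_terminal="W" if ("TIR" in arch and gidx % 2 == 0) else "D",
                    n_exons=exon_cycle[gidx % len(exon_cycle)],
                    premature_stop_before_lrr=pseudo,
                )
            )
            pos += gap_cycle[j % len(gap_cycle)]
            gidx += 1

    keeper_ids = [
        p.gene_id
        for p in plans
        if "NBS" in p.architecture
        and "TIR" not in p.architecture
        and not p.premature_stop_before_lrr
    ]
    return SyntheticSpec(
        seed=seed,
        chromosomes=chromosomes,
        gene_plan=plans,
        background_gc=0.4,
        expression_plan=ExpressionPlan(
            n_conditions=4,
            n_replicates=3,
            high_gene_ids=tuple(keeper_ids[:5]),
            noise_sd=0.3,
        ),
    )
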