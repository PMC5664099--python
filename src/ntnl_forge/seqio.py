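"""Readers/writers for FASTA, GFF3 and TSV reports, plus CDS assembly and translation.

All coordinates follow the conventions used throughout the package: GFF3 and
:class:`GeneModel` genomic coordinates are 1-based inclusive (the format
standard), protein and motif coordinates elsewhere are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

_NT = set("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class GeneModel:
    """One annotated protein-coding gene.

    ``exons`` are (start, end) pairs in ascending genomic order, 1-based
    inclusive. ``cds`` is the spliced coding sequence in transcript
    orientation (reverse-complemented for minus-strand genes); ``protein``
    its translation with internal stops kept as ``*``.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: str = ""
    protein: str = ""

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a replicate-group structure.

    ``replicate_groups`` maps each sample id to its condition label; every
    sample belongs to exactly one condition.
    """

    values: pd.DataFrame  # index: gene_id, columns: sample_id
    replicate_groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.replicate_groups]
        if missing:
            raise ValueError(f"samples without a replicate group: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    Internal stop codons are rendered as ``*`` and retained — pseudogene
    detection downstream depends on seeing them.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    bad = set(cds.upper()) - _NT
    if bad:
        raise ValueError(f"non-ACGT characters in CDS: {sorted(bad)}")
    if not cds:
        return ""
    return str(Seq(cds.upper()).translate())


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(gff_path: str | Path, genome_fasta: str | Path) -> list[GeneModel]:
    """Parse gene models from a GFF3 file, assembling and translating each CDS.

    Only gene/mRNA/exon/CDS feature types are consumed; others are ignored
    with a logged count. When a gene carries several mRNAs the longest-CDS
    isoform is kept. Minus-strand CDS are reverse-complemented before
    translation.
    """
    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genome = Fasta(str(genome_fasta))
    known = {"gene", "mRNA", "exon", "CDS"}
    other = sum(1 for f in db.all_features() if f.featuretype not in known)
    if other:
        logger.info("ignored %d features of unhandled types", other)

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.seqid not in genome:
            raise ValueError(f"gene {gene.id}: unknown sequence {gene.seqid!r}")
        chrom_len = len(genome[gene.seqid])
        if gene.end > chrom_len:
            raise ValueError(
                f"gene {gene.id}: end {gene.end} beyond {gene.seqid} length {chrom_len}"
            )
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            mrnas = [gene]  # tolerate gene features carrying exons directly
        best = None
        for mrna in mrnas:
            cds_feats = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
            exon_feats = sorted(db.children(mrna, featuretype="exon"), key=lambda f: f.start)
            if not cds_feats:
                continue
            cds_len = sum(f.end - f.start + 1 for f in cds_feats)
            if best is None or cds_len > best[0]:
                best = (cds_len, cds_feats, exon_feats)
        if best is None:
            logger.warning("gene %s has no CDS features; skipped", gene.id)
            continue
        _, cds_feats, exon_feats = best
        for f in cds_feats:
            if f.end > chrom_len:
                raise ValueError(
                    f"CDS of {gene.id}: end {f.end} beyond {gene.seqid} length {chrom_len}"
                )
        pieces = [str(genome[gene.seqid][f.start - 1 : f.end]) for f in cds_feats]
        cds = "".join(pieces).upper()
        if gene.strand == "-":
            cds = reverse_complement(cds)
        protein = translate(cds) if len(cds) % 3 == 0 else ""
        exons = [(f.start, f.end) for f in (exon_feats or cds_feats)]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                protein=protein,
            )
        )
    return models


def write_report(
    rows: Iterable[Mapping[str, object]],
    columns: Sequence[str],
    path: str | Path,
) -> pd.DataFrame:
    """Write a deterministic TSV report (header row, UTF-8, sorted rows).

    Rows are sorted by gene_id then by a coordinate column when one exists,
    so re-running on identical inputs is byte-identical.
    """
    df = pd.DataFrame(list(rows), columns=list(columns))
    sort_cols = [c for c in ("gene_id", "chromosome", "start") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")
    return df


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (first column gene_id) plus a sample→condition map."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t")
    groups = dict(zip(groups_df["sample_id"], groups_df["condition"]))
    return ExpressionMatrix(values=values, replicate_groups=groups)


def write_expression(em: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path) -> None:
    em.values.to_csv(matrix_path, sep="\t", index_label="gene_id", lineterminator="\n")
    pd.DataFrame(
        {"sample_id": list(em.replicate_groups), "condition": list(em.replicate_groups.values())}
    ).to_csv(groups_path, sep="\t", index=False, lineterminator="\n")
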