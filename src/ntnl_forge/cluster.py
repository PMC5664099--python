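"""Gene-cluster detection on genomic coordinates with the 200-kb rule.

A cluster is a maximal run of genes on one chromosome in which every
adjacent pair is closer than the window (single-linkage chaining,
boundary inclusive). Singletons are not clusters. The gap is measured
start-to-start by default; end-to-start is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .seqio import GeneModel

DEFAULT_WINDOW = 200_000


@dataclass
class GeneCluster:
    chromosome: str
    members: list[str]            # gene ids ordered by start
    span: tuple[int, int]         # (min start, max end) bp

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSummary:
    species: str
    n_clusters: int
    genes_in_clusters: int
    percent_in_clusters: int      # integer %, half-up
    largest_cluster_size: int
    avg_genes_per_cluster: float  # 2 decimals, half-up


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def find_clusters(
    genes: Sequence[GeneModel],
    window: int = DEFAULT_WINDOW,
    gap_mode: str = "start",
) -> list[GeneCluster]:
    """Single-linkage chaining of genes on one chromosome.

    Adjacent genes are linked when their gap (start-to-start by default,
    end-to-start with ``gap_mode='end'``) is <= ``window``. Maximal chains
    of size >= 2 become clusters.
    """
    if not genes:
        return []
    chroms = {g.chromosome for g in genes}
    if len(chroms) > 1:
        raise ValueError(f"genes from mixed chromosomes: {sorted(chroms)}")
    if gap_mode not in ("start", "end"):
        raise ValueError("gap_mode must be 'start' or 'end'")
    ordered = sorted(genes, key=lambda g: (g.start, g.gene_id))
    clusters: list[GeneCluster] = []
    chain = [ordered[0]]
    for prev, cur in zip(ordered, ordered[1:]):
        gap = cur.start - (prev.start if gap_mode == "start" else prev.end)
        if gap <= window:
            chain.append(cur)
        else:
            if len(chain) >= 2:
                clusters.append(_as_cluster(chain))
            chain = [cur]
    if len(chain) >= 2:
        clusters.append(_as_cluster(chain))
    return clusters


def _as_cluster(chain: list[GeneModel]) -> GeneCluster:
    return GeneCluster(
        chromosome=chain[0].chromosome,
        members=[g.gene_id for g in chain],
        span=(min(g.start for g in chain), max(g.end for g in chain)),
    )


def find_clusters_by_chromosome(
    genes: Iterable[GeneModel],
    window: int = DEFAULT_WINDOW,
    gap_mode: str = "start",
) -> list[GeneCluster]:
    """Convenience wrapper: partition by chromosome, then chain each."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    out: list[GeneCluster] = []
    for chrom in sorted(by_chrom):
        out.extend(find_clusters(by_chrom[chrom], window, gap_mode))
    return out


def summarize_clusters(
    clusters: Sequence[GeneCluster], total_genes: int, species: str
) -> ClusterSummary:
    """Per-genome clustering summary (counts, percent clustered, averages).

    The percentage is rounded half-up to an integer and the average genes
    per cluster half-up to 2 decimals, computed from the counts — printed
    table cells that disagree with their own counts are not reproduced.
    """
    if total_genes <= 0:
        raise ValueError("total_genes must be > 0")
    in_clusters = sum(c.size for c in clusters)
    if total_genes < in_clusters:
        raise ValueError("total_genes smaller than genes in clusters")
    n = len(clusters)
    return ClusterSummary(
        species=species,
        n_clusters=n,
        genes_in_clusters=in_clusters,
        percent_in_clusters=int(_round_half_up(100 * in_clusters / total_genes)),
        largest_cluster_size=max((c.size for c in clusters), default=0),
        avg_genes_per_cluster=_round_half_up(in_clusters / n, 2) if n else 0.0,
    )


def chromosomes_without_genes(
    all_chromosomes: Iterable[str], kept_genes: Iterable[GeneModel]
) -> list[str]:
    """Chromosomes carrying zero kept genes, sorted by name."""
    occupied = {g.chromosome for g in kept_genes}
    return sorted(set(all_chromosomes) - occupied)
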