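"""End-to-end orchestration: simulate → scan → classify → cluster → stats.

One :class:`RunConfig` (or YAML file) drives a full reproducible run; the
manifest JSON records the seed, parameter echo, input hashes and
per-stage record counts, so a rerun with the same config and seed yields
identical counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import classify, cluster, evostats, motifscan, seqio, synthdata

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "hits.tsv", "calls.tsv", "clusters.tsv", "summary.tsv", "stats.tsv",
    "expr_summary.tsv", "manifest.json",
)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "ntnl_run"
    # synthetic input (default); file inputs override when all three given
    use_default_spec: bool = True
    proteome_fasta: str | None = None
    gff3: str | None = None
    genome_fasta: str | None = None
    # thresholds
    e1: float = 0.05
    e2: float = 0.001
    n_decoys: int = 200
    window: int = cluster.DEFAULT_WINDOW
    pad: int = 20
    motif_mismatches: int = motifscan.DEFAULT_MAX_MISMATCHES
    high_quantile: float = 0.9
    basal_quantile: float = 0.1
    species: str = "synthetic"

    def validate(self) -> None:
        if self.e2 > self.e1:
            raise ValueError(f"e2 ({self.e2}) must not exceed e1 ({self.e1})")
        for name in ("e1", "e2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("window", "pad", "n_decoys"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.basal_quantile < self.high_quantile <= 1):
            raise ValueError("quantiles must satisfy 0 <= basal < high <= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and return the manifest."""
    config.validate()
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "parameters": asdict(config), "stages": {}}

    # -- stage 1: inputs -----------------------------------------------------
    stage_t = time.time()
    if config.proteome_fasta and config.gff3 and config.genome_fasta:
        genes = seqio.read_gff3(config.gff3, config.genome_fasta)
        proteins = seqio.read_fasta(config.proteome_fasta)
        truth = None
        seed_alignment = synthdata.make_seed_alignment(8, config.seed + 10)
        manifest["inputs"] = {
            p: _sha256(Path(p))
            for p in (config.proteome_fasta, config.gff3, config.genome_fasta)
        }
    else:
        spec = synthdata.default_spec(config.seed)
        bundle = synthdata.generate_genome(spec)
        paths = bundle.write(outdir / "simulated")
        genes = bundle.genes
        proteins = bundle.proteins
        truth = bundle.truth_by_id()
        seed_alignment = synthdata.make_seed_alignment(8, config.seed + 10)
        manifest["inputs"] = {k: _sha256(p) for k, p in sorted(paths.items())}
    manifest["stages"]["simulate"] = {
        "n_genes": len(genes), "n_proteins": len(proteins),
        "seconds": round(time.time() - stage_t, 2),
    }
    logger.info("inputs ready: %d genes", len(genes))

    # -- stage 2: two-pass profile search ------------------------------------
    stage_t = time.time()
    seed_profile = motifscan.build_profile(seed_alignment)
    scanned, _profile2 = motifscan.two_pass_search(
        seed_profile, proteins, e1=config.e1, e2=config.e2,
        n_decoys=config.n_decoys, seed=config.seed + 20,
    )
    hit_rows = [{"gene_id": g, "retained": True} for g in sorted(scanned)]
    seqio.write_report(hit_rows, ["gene_id", "retained"], outdir / "hits.tsv")
    manifest["stages"]["scan"] = {
        "n_scanned": len(proteins), "n_retained": len(scanned),
        "seconds": round(time.time() - stage_t, 2),
    }
    logger.info("profile search retained %d/%d", len(scanned), len(proteins))

    # -- stage 3: classification ---------------------------------------------
    stage_t = time.time()
    calls: dict[str, classify.ArchitectureCall] = {}
    for g in genes:
        protein = proteins.get(g.gene_id, g.protein)
        if g.gene_id not in scanned:
            call = classify.ArchitectureCall(
                gene_id=g.gene_id,
                flags={d: False for d in ("CC", "NBS", "LRR", "RPW8", "BED", "TIR")},
                status=classify.REJECTED_NO_NBARC,
                reasons=["not retained by the profile search"],
            )
        else:
            hits = motifscan.scan_architecture(protein, config.motif_mismatches)
            call = classify.classify_gene(g.gene_id, protein, hits)
        calls[g.gene_id] = call
    call_rows = [
        {
            "gene_id": c.gene_id,
            "flags": "+".join(sorted(d for d, v in c.flags.items() if v)),
            "kinase2_terminal": c.kinase2_terminal or "",
            "subgroup": c.subgroup_label,
            "status": c.status,
            "reasons": "; ".join(c.reasons),
        }
        for c in calls.values()
    ]
    seqio.write_report(
        call_rows,
        ["gene_id", "flags", "kinase2_terminal", "subgroup", "status", "reasons"],
        outdir / "calls.tsv",
    )
    status_counts: dict[str, int] = {}
    for c in calls.values():
        status_counts[c.status] = status_counts.get(c.status, 0) + 1
    kept_ids = {g for g, c in calls.items() if c.status == classify.KEPT}
    manifest["stages"]["classify"] = {
        "status_counts": dict(sorted(status_counts.items())),
        "n_kept": len(kept_ids),
        "seconds": round(time.time() - stage_t, 2),
    }
    if truth is not None:
        truth_keep = sum(1 for t in truth.values() if t.expected_keep)
        manifest["stages"]["classify"]["truth_expected_keep"] = truth_keep

    # -- stage 4: clustering -------------------------------------------------
    stage_t = time.time()
    kept_genes = [g for g in genes if g.gene_id in kept_ids]
    clusters = cluster.find_clusters_by_chromosome(kept_genes, config.window)
    summary = cluster.summarize_clusters(clusters, len(kept_genes), config.species)
    cluster_rows = [
        {
            "chromosome": c.chromosome,
            "start": c.span[0],
            "end": c.span[1],
            "size": c.size,
            "members": ",".join(c.members),
        }
        for c in clusters
    ]
    seqio.write_report(
        cluster_rows, ["chromosome", "start", "end", "size", "members"],
        outdir / "clusters.tsv",
    )
    seqio.write_report(
        [asdict(summary)],
        ["species", "n_clusters", "genes_in_clusters", "percent_in_clusters",
         "largest_cluster_size", "avg_genes_per_cluster"],
        outdir / "summary.tsv",
    )
    clustered = sum(c.size for c in clusters)
    manifest["stages"]["cluster"] = {
        "n_clusters": len(clusters),
        "genes_in_clusters": clustered,
        "unclustered": len(kept_genes) - clustered,
        "empty_chromosomes": cluster.chromosomes_without_genes(
            [name for name, _ in bundle.spec.chromosomes]
            if truth is not None
            else sorted({g.chromosome for g in genes}),
            kept_genes,
        ),
        "seconds": round(time.time() - stage_t, 2),
    }

    # -- stage 5: per-gene statistics ----------------------------------------
    stage_t = time.time()
    stats_rows = []
    for g in genes:
        if g.gene_id not in kept_ids:
            continue
        stats_rows.append(
            {
                "gene_id": g.gene_id,
                "chromosome": g.chromosome,
                "start": g.start,
                "subgroup": calls[g.gene_id].subgroup_label,
                "n_exons": g.n_exons,
                "gc_content": round(evostats.gc_content(g.cds), 4),
            }
        )
    seqio.write_report(
        stats_rows,
        ["gene_id", "chromosome", "start", "subgroup", "n_exons", "gc_content"],
        outdir / "stats.tsv",
    )
    exon_groups: dict[str, list[int]] = {}
    for row in stats_rows:
        exon_groups.setdefault(row["subgroup"], []).append(row["n_exons"])
    manifest["stages"]["stats"] = {
        "n_genes": len(stats_rows),
        "exon_stats": {k: list(v) for k, v in sorted(evostats.exon_stats(exon_groups).items())},
        "seconds": round(time.time() - stage_t, 2),
    }

    # -- stage 6: expression (synthetic input only) --------------------------
    if truth is not None:
        stage_t = time.time()
        expr = evostats.summarize_expression(
            bundle.expression, config.high_quantile, config.basal_quantile
        )
        expr.to_csv(outdir / "expr_summary.tsv", sep="\t", lineterminator="\n")
        manifest["stages"]["expression"] = {
            "n_genes": len(expr),
            "n_high": int((expr["category"] == "high").sum()),
            "n_basal": int((expr["category"] == "basal").sum()),
            "seconds": round(time.time() - stage_t, 2),
        }

    manifest["total_seconds"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
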