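"""Near-site cluster adjustment: infer genuine TSS clusters from Read-2 data.

In single-end 5' libraries only Read 2 carries cDNA, so its 5' end lies a
roughly predictable distance 3' of the genuine TSS (set by the cDNA fragment
length).  The adjustment procedure:

1. exclude near-site clusters whose centers are intronic (unannotated TSSs
   cannot be located);
2. learn the *adjustment distance*: over genes with a single annotated TSS,
   the smallest transcript-space distance between any near-site cluster
   center and the annotated TSS, dropping distances > 1,000 bp, averaged
   with weights equal to the supporting read counts;
3. shift every cluster center 5' by that distance *in transcript
   coordinates*, so introns are skipped, and project back to the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .clustering import TssCluster, assign_gene
from .genomic import GeneModel, GenomicInterval, TssAnnotation, classify_position

logger = logging.getLogger(__name__)

MAX_ADJUSTMENT_DISTANCE = 1000


@dataclass
class AdjustmentModel:
    """Learned read-weighted mean displacement of near-site clusters.

    ``distance_samples`` holds the retained (distance bp, weight reads)
    pairs, one per usable single-TSS gene.
    """

    adjustment_distance: float
    n_genes_used: int
    distance_samples: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.adjustment_distance < 0:
            raise ValueError("adjustment_distance must be >= 0")


def filter_intronic_nearsite(
    clusters: Sequence[TssCluster], gene_models: Sequence[GeneModel]
) -> tuple[list[TssCluster], list[TssCluster]]:
    """Split clusters into (kept, excluded-as-intronic) by their centers.

    Intronic near-site clusters indicate missing annotation; the genuine TSS
    cannot be determined, so they are excluded from adjustment and downstream
    analysis.  Intergenic centers are kept (they are not intronic).
    """
    kept, excluded = [], []
    for c in clusters:
        category = classify_position(c.center, c.strand, c.chrom, gene_models)
        (excluded if category == "intron" else kept).append(c)
    if excluded:
        logger.info(
            "filter_intronic_nearsite: excluded %d of %d clusters",
            len(excluded), len(excluded) + len(kept),
        )
    return kept, excluded


def _transcript_distance(
    gene: GeneModel, pos_a: int, pos_b: int
) -> float | None:
    """Smallest |transcript-coordinate difference| over transcripts holding both."""
    best = None
    for tx in gene.transcripts:
        ta = tx.genomic_to_transcript(pos_a)
        tb = tx.genomic_to_transcript(pos_b)
        if ta is None or tb is None:
            continue
        d = abs(ta - tb)
        if best is None or d < best:
            best = d
    return best


def learn_adjustment_distance(
    nearsite_clusters: Sequence[TssCluster],
    tss_annotation: TssAnnotation,
    gene_models: Sequence[GeneModel],
    max_distance: int = MAX_ADJUSTMENT_DISTANCE,
) -> AdjustmentModel:
    """Learn the adjustment distance from genes with one annotated TSS.

    For each single-annotated-TSS gene, the smallest transcript-space
    distance between its near-site cluster centers and the annotated TSS is
    computed; distances greater than ``max_distance`` bp are ignored (they
    most likely indicate novel, unannotated TSSs).  The read-count-weighted
    mean over genes is the adjustment distance; the weight is the read count
    of the closest cluster.
    """
    genes_by_id = {g.gene_id: g for g in gene_models}
    single = tss_annotation.single_tss_genes()

    clusters_by_gene: dict[str, list[TssCluster]] = {}
    for c in nearsite_clusters:
        gid = c.gene_id
        if gid is None:
            gid = assign_gene(c, gene_models, point="center")
        if gid is not None:
            clusters_by_gene.setdefault(gid, []).append(c)

    samples: list[tuple[float, float]] = []
    for gid, (chrom, tss, strand) in single.items():
        gene = genes_by_id.get(gid)
        if gene is None or gid not in clusters_by_gene:
            continue
        best: tuple[float, float] | None = None
        for c in clusters_by_gene[gid]:
            d = _transcript_distance(gene, c.center, tss)
            if d is None:
                # center or TSS not exonic on a shared transcript:
                # fall back to genomic distance
                d = abs(c.center - tss)
            if best is None or d < best[0]:
                best = (float(d), float(c.total_count))
        if best is not None and best[0] <= max_distance:
            samples.append(best)

    if not samples:
        raise ValueError(
            "no usable single-annotated-TSS genes with near-site clusters "
            "within the distance cutoff; supply an adjustment distance "
            "manually (e.g. --distance)"
        )
    wsum = sum(w for _, w in samples)
    dist = sum(d * w for d, w in samples) / wsum
    return AdjustmentModel(dist, len(samples), samples)


def adjust_cluster(
    cluster: TssCluster,
    adjustment: AdjustmentModel | float,
    gene_models: Sequence[GeneModel],
) -> TssCluster:
    """Shift a near-site cluster 5' by the adjustment distance, intron-aware.

    The center is projected into transcript coordinates of a transcript of
    the assigned gene whose exons contain it (preferring the transcript with
    the most 5' annotated start, which maximizes room for upstream
    shifting), moved ``adjustment`` bases toward the transcript 5' end
    (clamped at transcript position 1), and projected back to the genome.
    The adjusted cluster keeps the original width, centered on the new
    position.  If no transcript exon contains the center, the shift falls
    back to genomic coordinates with a warning.
    """
    distance = (
        adjustment.adjustment_distance
        if isinstance(adjustment, AdjustmentModel)
        else float(adjustment)
    )
    shift = int(round(distance))
    center = cluster.center
    genes_by_id = {g.gene_id: g for g in gene_models}
    gene = genes_by_id.get(cluster.gene_id) if cluster.gene_id else None

    new_center: int | None = None
    if gene is not None:
        containing = [
            tx for tx in gene.transcripts
            if tx.genomic_to_transcript(center) is not None
        ]
        if containing:
            # most 5' annotated start: min tss on '+', max on '-'
            tx = min(
                containing,
                key=lambda t: t.tss if gene.strand == "+" else -t.tss,
            )
            tpos = tx.genomic_to_transcript(center)
            new_center = tx.transcript_to_genomic(max(1, tpos - shift))
    if new_center is None:
        logger.warning(
            "adjust_cluster: center %s:%d not exonic in assigned gene; "
            "falling back to genomic shift", cluster.chrom, center,
        )
        new_center = center - shift if cluster.strand == "+" else center + shift
        new_center = max(1, new_center)

    width = cluster.interval.width
    start = max(1, new_center - (width - 1) // 2)
    end = start + width - 1
    return TssCluster(
        GenomicInterval(cluster.chrom, start, end, cluster.strand),
        {new_center: cluster.total_count},
        gene_id=cluster.gene_id,
        sample_id=cluster.sample_id,
    )


def adjust_clusters(
    clusters: Sequence[TssCluster],
    adjustment: AdjustmentModel | float,
    gene_models: Sequence[GeneModel],
) -> list[TssCluster]:
    """Adjust clusters, preserving 1:1 order correspondence with the input."""
    return [adjust_cluster(c, adjustment, gene_models) for c in clusters]


def write_adjustment_report(model: AdjustmentModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("distance_bp\tweight_reads\n")
        for d, w in model.distance_samples:
            fh.write(f"{d:.1f}\t{w:.1f}\n")
        fh.write(f"# adjustment_distance\t{model.adjustment_distance:.3f}\n")
        fh.write(f"# n_genes_used\t{model.n_genes_used}\n")
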