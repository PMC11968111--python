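"""Accuracy metrics for predicted TSS clusters against a reference annotation.

Covers signed distance-to-annotation distributions (restricted to genes with
a single annotated TSS), gene-level precision/recall averaged into per-sample
scores with F1 = 2PR/(P+R), and genomic-category summaries of cluster
positions and read mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import TssCluster
from .genomic import CATEGORIES, GeneModel, TssAnnotation, classify_position


@dataclass
class AccuracyReport:
    precision: float
    recall: float
    f1: float
    per_gene: dict[str, tuple[float | None, float | None]] = field(
        default_factory=dict
    )


def signed_distance(predicted_pos: int, annotated_pos: int, strand: str) -> int:
    """Signed bp distance; positive = predicted on the 5' side of the annotation."""
    if strand == "+":
        return annotated_pos - predicted_pos
    return predicted_pos - annotated_pos


def distance_distribution(
    clusters: Sequence[TssCluster],
    annotation: TssAnnotation,
    mode: str = "dominant",
    window: int = 500,
) -> dict:
    """Signed distances from cluster reference points to annotated TSSs.

    Restricted to genes with exactly one annotated TSS; for each of their
    clusters the signed distance from the reference point (``dominant`` for
    on-site, ``center`` for near-site) to the TSS is retained when
    |d| <= ``window``.  Returns the samples with mean and sample (n-1) sd.
    """
    if mode not in ("dominant", "center"):
        raise ValueError("mode must be 'dominant' or 'center'")
    single = annotation.single_tss_genes()
    if not single:
        import warnings

        warnings.warn("no single-annotated-TSS genes; empty distance report")
        return {"distances": np.array([]), "mean": np.nan, "sd": np.nan}
    distances = []
    for c in clusters:
        if c.gene_id not in single:
            continue
        chrom, tss, strand = single[c.gene_id]
        if chrom != c.chrom or strand != c.strand:
            continue
        point = c.dominant_pos if mode == "dominant" else c.center
        d = signed_distance(point, tss, strand)
        if abs(d) <= window:
            distances.append(d)
    distances = np.array(distances, float)
    mean = float(distances.mean()) if len(distances) else np.nan
    sd = float(distances.std(ddof=1)) if len(distances) > 1 else (
        0.0 if len(distances) == 1 else np.nan
    )
    return {"distances": distances, "mean": mean, "sd": sd}


def precision_recall_f1(
    clusters: Sequence[TssCluster], annotation: TssAnnotation
) -> AccuracyReport:
    """Gene-level precision/recall averaged into sample-level P, R, F1.

    A predicted cluster is a true positive if its interval overlaps an
    annotated TSS of the same gene; an annotated TSS is recalled if it is
    contained in a predicted cluster of the same gene.  Sample-level P and R
    are unweighted means of the gene-level values (genes without predictions
    contribute recall 0 but no precision term; genes absent from the
    annotation are excluded); F1 = 2PR/(P+R), 0 when P + R = 0.
    """
    by_gene_annot = annotation.by_gene()
    by_gene_pred: dict[str, list[TssCluster]] = {}
    for c in clusters:
        if c.gene_id is not None:
            by_gene_pred.setdefault(c.gene_id, []).append(c)

    per_gene: dict[str, tuple[float | None, float | None]] = {}
    precisions, recalls = [], []
    for gene_id, tss_list in by_gene_annot.items():
        preds = by_gene_pred.get(gene_id, [])
        positions = [pos for _, pos, _ in tss_list]
        if preds:
            hit = [
                any(c.interval.contains(p) for p in positions) for c in preds
            ]
            gene_p = sum(hit) / len(preds)
            precisions.append(gene_p)
        else:
            gene_p = None
        covered = [
            any(c.interval.contains(p) for c in preds) for p in positions
        ]
        gene_r = sum(covered) / len(positions)
        recalls.append(gene_r)
        per_gene[gene_id] = (gene_p, gene_r)

    P = float(np.mean(precisions)) if precisions else 0.0
    R = float(np.mean(recalls)) if recalls else 0.0
    f1 = 2 * P * R / (P + R) if P + R > 0 else 0.0
    return AccuracyReport(P, R, f1, per_gene)


def category_usage_summary(
    clusters: Sequence[TssCluster],
    gene_models: Sequence[GeneModel],
    point: str = "dominant",
) -> dict[str, dict[str, float]]:
    """Fractions of clusters and of read mass per genomic category.

    Categories come from classifying each cluster's reference point
    (dominant position for on-site data, center for near-site) against the
    gene models; both fraction sets sum to 1 over the categories.
    """
    n = {cat: 0 for cat in CATEGORIES}
    reads = {cat: 0 for cat in CATEGORIES}
    for c in clusters:
        pos = c.dominant_pos if point == "dominant" else c.center
        cat = classify_position(pos, c.strand, c.chrom, gene_models)
        n[cat] += 1
        reads[cat] += c.total_count
    total_n = sum(n.values()) or 1
    total_reads = sum(reads.values()) or 1
    return {
        "cluster_fraction": {cat: n[cat] / total_n for cat in CATEGORIES},
        "read_fraction": {cat: reads[cat] / total_reads for cat in CATEGORIES},
    }
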