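"""Deterministic synthetic-data generation for end-to-end testing.

Builds a small synthetic genome (non-overlapping multi-exon genes with known
true TSSs), writes its GTF / TSS-BED annotation, and generates barcoded
mapped-TSS tables for both library types:

* on-site reads: 5' ends at the true TSSs with Gaussian positional jitter;
* near-site reads: 5' ends displaced 3' of the true TSS by |N(mean, sd)| in
  transcript coordinates, projected to the genome through the exon chain
  (so displaced positions are always exonic).

Everything is reproducible from a seed, and the known truth (gene models,
true TSSs, per-gene usage) is returned alongside the records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genomic import (
    GeneModel,
    GenomicInterval,
    MappedTssRecord,
    Transcript,
    TssAnnotation,
    write_gtf,
    write_tss_bed,
)


@dataclass
class SyntheticGenome:
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    true_tss: dict[str, list[int]]       # gene_id -> true TSS positions (5'->3')
    usage: dict[str, np.ndarray]         # gene_id -> expected usage per TSS
    seed: int = 0

    def annotation(self) -> TssAnnotation:
        entries = []
        for gene in self.genes:
            for pos in self.true_tss[gene.gene_id]:
                entries.append((gene.gene_id, gene.chrom, pos, gene.strand))
        return TssAnnotation(entries)


def make_genome(
    n_genes: int = 20,
    multi_tss_fraction: float = 0.3,
    seed: int = 0,
    chrom: str = "chrS",
    min_tss_spacing: int = 200,
) -> SyntheticGenome:
    """Build non-overlapping genes with 1-3 exons and 1-2 true TSSs each.

    Multi-TSS genes get a second transcript whose first exon starts
    ``min_tss_spacing``..600 bp into the primary first exon (transcript
    space), so the two true TSSs are well separated for clustering.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    true_tss: dict[str, list[int]] = {}
    usage: dict[str, np.ndarray] = {}
    cursor = 5000
    for i in range(n_genes):
        gene_id = f"SYNG{i:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        first_len = int(rng.integers(800, 1200))
        exon_lens = [first_len] + [int(rng.integers(100, 300))
                                   for _ in range(n_exons - 1)]
        intron_lens = [int(rng.integers(200, 1000)) for _ in range(n_exons - 1)]
        # lay out genomically left to right
        bounds = []
        p = cursor
        for e in range(n_exons):
            bounds.append((p, p + exon_lens[e] - 1))
            p = bounds[-1][1] + 1 + (intron_lens[e] if e < n_exons - 1 else 0)
        gene_end = bounds[-1][1]
        if strand == "-":
            # first exon in transcript orientation is the rightmost
            exon_order = list(reversed(range(n_exons)))
            lens_by_pos = list(reversed(exon_lens))
            bounds = []
            p = cursor
            for L in lens_by_pos:
                bounds.append((p, p + L - 1))
                p = bounds[-1][1] + 1 + (
                    intron_lens[len(bounds) - 1]
                    if len(bounds) < n_exons else 0
                )
            gene_end = bounds[-1][1]
            exons = [GenomicInterval(chrom, s, e, strand)
                     for s, e in reversed(bounds)]
        else:
            exons = [GenomicInterval(chrom, s, e, strand) for s, e in bounds]
        tx1 = Transcript(f"{gene_id}.T1", exons)
        gene = GeneModel(gene_id, chrom, strand, [tx1])
        tss_list = [tx1.tss]
        if rng.random() < multi_tss_fraction:
            offset = int(rng.integers(min_tss_spacing, 600))
            first = exons[0]
            if strand == "+":
                alt_first = GenomicInterval(chrom, first.start + offset,
                                            first.end, strand)
            else:
                alt_first = GenomicInterval(chrom, first.start,
                                            first.end - offset, strand)
            tx2 = Transcript(f"{gene_id}.T2", [alt_first] + exons[1:])
            gene.transcripts.append(tx2)
            tss_list.append(tx2.tss)
        genes.append(gene)
        true_tss[gene_id] = tss_list
        w = rng.dirichlet(np.full(len(tss_list), 5.0))
        usage[gene_id] = w
        cursor = gene_end + int(rng.integers(2000, 4000))
    return SyntheticGenome({chrom: cursor + 5000}, genes, true_tss, usage, seed)


def make_annotation(
    n_genes: int = 20,
    multi_tss_fraction: float = 0.3,
    seed: int = 0,
    out_dir=None,
) -> SyntheticGenome:
    """Build a genome and optionally write its GTF and TSS BED to ``out_dir``."""
    genome = make_genome(n_genes, multi_tss_fraction, seed)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_gtf(genome.genes, os.path.join(out_dir, "annotation.gtf"))
        write_tss_bed(genome.annotation(), os.path.join(out_dir, "tss.bed"))
    return genome


def _barcode(i: int) -> str:
    return f"BC{i:06d}-1"


def make_onsite_reads(
    genome: SyntheticGenome,
    cells_per_sample: int = 50,
    reads_per_cell: int = 200,
    tss_jitter_sd: float = 2.0,
    seed: int = 0,
) -> list[MappedTssRecord]:
    """Barcoded on-site records: 5' ends at true TSSs with Gaussian jitter.

    Each read picks a gene uniformly, then a TSS according to the genome's
    per-gene usage, then jitters the position (rounded, clamped to >= 1).
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    gene_of = {g.gene_id: g for g in genome.genes}
    counts: dict[tuple, int] = {}
    for c in range(cells_per_sample):
        bc = _barcode(c)
        gidx = rng.integers(0, len(gene_ids), reads_per_cell)
        for gi in gidx:
            gid = gene_ids[gi]
            gene = gene_of[gid]
            tss_i = rng.choice(len(genome.true_tss[gid]), p=genome.usage[gid])
            pos = genome.true_tss[gid][tss_i]
            if tss_jitter_sd > 0:
                pos = max(1, int(round(pos + rng.normal(0, tss_jitter_sd))))
            key = (gene.chrom, int(pos), gene.strand, bc)
            counts[key] = counts.get(key, 0) + 1
    return [
        MappedTssRecord(chrom, pos, n, strand, bc)
        for (chrom, pos, strand, bc), n in sorted(counts.items())
    ]


def make_nearsite_reads(
    genome: SyntheticGenome,
    cells_per_sample: int = 50,
    reads_per_cell: int = 200,
    displacement_mean: float = 150.0,
    displacement_sd: float = 30.0,
    seed: int = 0,
) -> list[MappedTssRecord]:
    """Barcoded near-site records: 5' ends displaced 3' in transcript space.

    The displacement is |N(mean, sd)| added to the true TSS's transcript
    coordinate on its own transcript, clamped to the transcript 3' end, then
    projected back to genomic coordinates through the exon chain.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genome.genes]
    gene_of = {g.gene_id: g for g in genome.genes}
    counts: dict[tuple, int] = {}
    for c in range(cells_per_sample):
        bc = _barcode(c)
        gidx = rng.integers(0, len(gene_ids), reads_per_cell)
        for gi in gidx:
            gid = gene_ids[gi]
            gene = gene_of[gid]
            tss_i = int(rng.choice(len(genome.true_tss[gid]), p=genome.usage[gid]))
            tx = gene.transcripts[tss_i]
            disp = abs(rng.normal(displacement_mean, displacement_sd))
            tpos = min(tx.length, 1 + int(round(disp)))
            pos = tx.transcript_to_genomic(tpos)
            key = (gene.chrom, int(pos), gene.strand, bc)
            counts[key] = counts.get(key, 0) + 1
    return [
        MappedTssRecord(chrom, pos, n, strand, bc)
        for (chrom, pos, strand, bc), n in sorted(counts.items())
    ]
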