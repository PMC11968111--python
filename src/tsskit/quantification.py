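"""Per-cell quantification of unified TSS clusters.

Produces a sparse clusters x cells UMI count matrix for each sample: entry
(t, c) is the number of deduplicated reads from cell c whose mapped 5' end
falls inside cluster t (closed interval, strand-matched).  For near-site
data the counting windows are the ORIGINAL near-site intervals, while the
output rows correspond 1:1 to the adjusted clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .genomic import GenomicInterval, MappedTssRecord

logger = logging.getLogger(__name__)


@dataclass
class CellClusterMatrix:
    """Sparse clusters x cells count matrix for one sample."""

    sample_id: str
    clusters: list[GenomicInterval]
    barcodes: list[str]
    counts: sp.csr_matrix
    gene_of_cluster: dict[int, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.clusters), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.clusters)} clusters x {len(self.barcodes)} barcodes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")


def _check_disjoint(intervals: Sequence[GenomicInterval]) -> None:
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    for ivs in by_key.values():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping counting intervals {a} and {b}: "
                    "unified clusters must be disjoint per strand"
                )


def quantify(
    records: Iterable[MappedTssRecord],
    unified_clusters: Sequence[GenomicInterval],
    mode: str = "onsite",
    counting_intervals: Sequence[GenomicInterval] | None = None,
    sample_id: str = "sample",
    gene_of_cluster: dict[int, str | None] | None = None,
) -> CellClusterMatrix:
    """Count barcoded records into unified clusters.

    ``mode='nearsite'`` requires ``counting_intervals`` (the original
    near-site windows, aligned 1:1 with ``unified_clusters``); in
    ``mode='onsite'`` the clusters themselves are the counting windows.
    Records falling in no window are dropped with a logged tally.
    """
    if mode not in ("onsite", "nearsite"):
        raise ValueError(f"mode must be 'onsite' or 'nearsite', got {mode!r}")
    if mode == "nearsite":
        if counting_intervals is None:
            raise ValueError("nearsite mode requires counting_intervals")
        if len(counting_intervals) != len(unified_clusters):
            raise ValueError(
                "counting_intervals must align 1:1 with unified_clusters"
            )
        windows = list(counting_intervals)
    else:
        windows = list(unified_clusters)
    _check_disjoint(windows)

    # sorted lookup per (chrom, strand)
    lookup: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for idx, iv in enumerate(windows):
        lookup.setdefault((iv.chrom, iv.strand), ([], [], []))  # type: ignore
    tmp: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for idx, iv in enumerate(windows):
        tmp.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end, idx))
    for key, triples in tmp.items():
        triples.sort()
        starts = np.array([t[0] for t in triples])
        ends = np.array([t[1] for t in triples])
        idxs = np.array([t[2] for t in triples])
        lookup[key] = (starts, ends, idxs)

    barcode_index: dict[str, int] = {}
    entries: dict[tuple[int, int], int] = {}
    dropped = 0
    for r in records:
        if r.barcode is None:
            raise ValueError(
                "quantify requires barcoded records (5-column mapped-TSS table)"
            )
        key = (r.chrom, r.strand)
        hit = None
        if key in lookup:
            starts, ends, idxs = lookup[key]
            i = int(np.searchsorted(starts, r.pos, side="right")) - 1
            if i >= 0 and r.pos <= ends[i]:
                hit = int(idxs[i])
        if hit is None:
            dropped += r.count
            continue
        c = barcode_index.setdefault(r.barcode, len(barcode_index))
        entries[(hit, c)] = entries.get((hit, c), 0) + r.count
    if dropped:
        logger.info("quantify[%s]: %d read counts outside all clusters", sample_id, dropped)

    barcodes = sorted(barcode_index, key=barcode_index.get)  # insertion order
    rows = np.array([k[0] for k in entries], dtype=np.int64)
    cols = np.array([k[1] for k in entries], dtype=np.int64)
    data = np.array(list(entries.values()), dtype=np.int64)
    counts = sp.coo_matrix(
        (data, (rows, cols)), shape=(len(unified_clusters), len(barcodes))
    ).tocsr()
    return CellClusterMatrix(
        sample_id, list(unified_clusters), barcodes, counts,
        dict(gene_of_cluster or {}),
    )


def gene_totals(matrix: CellClusterMatrix) -> tuple[list[str], sp.csr_matrix]:
    """Sum cluster counts per gene: entry (g, c) = sum over clusters of gene g."""
    genes: list[str] = []
    gene_index: dict[str, int] = {}
    rows, cols = [], []
    for t, gene in matrix.gene_of_cluster.items():
        if gene is None:
            continue
        g = gene_index.setdefault(gene, len(gene_index))
        if g == len(genes):
            genes.append(gene)
        rows.append(g)
        cols.append(t)
    n_clusters = len(matrix.clusters)
    agg = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(genes), n_clusters)
    ).tocsr()
    return genes, (agg @ matrix.counts).tocsr()


def compute_usage(cluster_counts: np.ndarray) -> np.ndarray:
    """Usage of each cluster on a gene: theta_t = x_t / sum_t x_t.

    Returns NaN for every entry when the gene total is zero (usage is
    undefined with no reads).
    """
    x = np.asarray(cluster_counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = x / total
    return np.where(total > 0, theta, np.nan)


# ---------------------------------------------------------------------------
# I/O: 10x-style triplet (matrix.mtx, clusters.bed, barcodes.tsv)
# ---------------------------------------------------------------------------


def write_matrix_dir(matrix: CellClusterMatrix, out_dir) -> None:
    import os

    from scipy.io import mmwrite

    from .clustering import write_intervals_bed

    os.makedirs(out_dir, exist_ok=True)
    mmwrite(os.path.join(out_dir, "matrix.mtx"), matrix.counts.tocoo())
    write_intervals_bed(matrix.clusters, os.path.join(out_dir, "clusters.bed"))
    with open(os.path.join(out_dir, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(matrix.barcodes) + ("\n" if matrix.barcodes else ""))
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        for t in range(len(matrix.clusters)):
            fh.write(f"{t}\t{matrix.gene_of_cluster.get(t) or '.'}\n")


def read_matrix_dir(in_dir, sample_id: str = "sample") -> CellClusterMatrix:
    import os

    from scipy.io import mmread

    from .clustering import read_intervals_bed

    counts = sp.csr_matrix(mmread(os.path.join(in_dir, "matrix.mtx")))
    clusters = read_intervals_bed(os.path.join(in_dir, "clusters.bed"))
    with open(os.path.join(in_dir, "barcodes.tsv")) as fh:
        barcodes = [l.strip() for l in fh if l.strip()]
    gene_of_cluster: dict[int, str | None] = {}
    genes_path = os.path.join(in_dir, "genes.tsv")
    if os.path.exists(genes_path):
        with open(genes_path) as fh:
            for line in fh:
                t, g = line.rstrip("\n").split("\t")
                gene_of_cluster[int(t)] = None if g == "." else g
    return CellClusterMatrix(sample_id, clusters, barcodes, counts, gene_of_cluster)


def write_long_tsv(matrix: CellClusterMatrix, path) -> None:
    """Long-format alternative: cluster, barcode, count."""
    coo = matrix.counts.tocoo()
    with open(path, "w") as fh:
        fh.write("cluster\tbarcode\tcount\n")
        for t, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{t}\t{matrix.barcodes[c]}\t{v}\n")
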