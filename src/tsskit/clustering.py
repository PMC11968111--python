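"""Distance-based TSS clustering and cross-sample merging.

Per-sample clustering chains nearby mapped-TSS positions into clusters
(simple distance clustering in the style of CAGE "distclu" methods).
Cross-sample merging partitions the pooled clusters into unified,
non-overlapping intervals with disjoin semantics: every breakpoint of every
input interval is a breakpoint of the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genomic import (
    GeneModel,
    GenomicInterval,
    MappedTssRecord,
    TssAnnotation,
)

DEFAULT_MAX_GAP = 20
DEFAULT_MIN_POS_COUNT = 3
DEFAULT_MIN_CLUSTER_COUNT = 5
DEFAULT_PROMOTER_WINDOW = 1000


@dataclass
class TssCluster:
    """A TSS cluster: an interval with per-position counts.

    ``dominant_pos`` is the position with the highest count (ties broken
    toward the 5' end in transcript orientation).  ``center`` is the
    read-count-weighted mean position rounded to the nearest integer; it is
    the reference point used for near-site clusters.
    """

    interval: GenomicInterval
    positions: dict[int, int]
    gene_id: str | None = None
    sample_id: str | None = None

    @property
    def total_count(self) -> int:
        return sum(self.positions.values())

    @property
    def dominant_pos(self) -> int:
        best = max(self.positions.values())
        candidates = [p for p, c in self.positions.items() if c == best]
        return min(candidates) if self.interval.strand == "+" else max(candidates)

    @property
    def center(self) -> int:
        total = self.total_count
        mean = sum(p * c for p, c in self.positions.items()) / total
        return int(round(mean))

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


def cluster_tss(
    records: Iterable[MappedTssRecord],
    max_gap: int = DEFAULT_MAX_GAP,
    min_pos_count: int = DEFAULT_MIN_POS_COUNT,
    min_cluster_count: int = DEFAULT_MIN_CLUSTER_COUNT,
    sample_id: str | None = None,
) -> list[TssCluster]:
    """Chain mapped-TSS positions into clusters on each chromosome/strand.

    Positions with count >= ``min_pos_count`` are kept; consecutive kept
    positions <= ``max_gap`` bp apart are chained; chains with total count
    >= ``min_cluster_count`` become clusters.  Barcodes are ignored here
    (counts are pooled across cells).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    pooled: dict[tuple[str, str], dict[int, int]] = {}
    for r in records:
        by_pos = pooled.setdefault((r.chrom, r.strand), {})
        by_pos[r.pos] = by_pos.get(r.pos, 0) + r.count

    clusters: list[TssCluster] = []
    for (chrom, strand), by_pos in sorted(pooled.items()):
        kept = sorted(
            (p, c) for p, c in by_pos.items() if c >= min_pos_count
        )
        chain: list[tuple[int, int]] = []
        for p, c in kept:
            if chain and p - chain[-1][0] > max_gap:
                clusters.extend(
                    _finish_chain(chain, chrom, strand, min_cluster_count, sample_id)
                )
                chain = []
            chain.append((p, c))
        clusters.extend(
            _finish_chain(chain, chrom, strand, min_cluster_count, sample_id)
        )
    return clusters


def _finish_chain(chain, chrom, strand, min_cluster_count, sample_id):
    if not chain:
        return []
    total = sum(c for _, c in chain)
    if total < min_cluster_count:
        return []
    interval = GenomicInterval(chrom, chain[0][0], chain[-1][0], strand)
    return [TssCluster(interval, dict(chain), sample_id=sample_id)]


def merge_clusters_disjoin(
    clusters_by_sample: Mapping[str, Sequence[TssCluster]]
) -> list[GenomicInterval]:
    """Partition pooled cluster intervals into unified disjoint intervals.

    Disjoin semantics: output intervals are pairwise non-overlapping (per
    strand), their union equals the union of the inputs, and every input
    breakpoint is an output breakpoint.  '+' and '-' intervals never merge.
    """
    intervals = [
        c.interval for clusters in clusters_by_sample.values() for c in clusters
    ]
    return disjoin_intervals(intervals)


def disjoin_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Breakpoint partition of a set of possibly overlapping intervals."""
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)

    out: list[GenomicInterval] = []
    for (chrom, strand), ivs in sorted(by_key.items()):
        # candidate breakpoints: every start, and every end+1
        points = sorted({iv.start for iv in ivs} | {iv.end + 1 for iv in ivs})
        starts = sorted(iv.start for iv in ivs)
        ends = sorted(iv.end for iv in ivs)
        import bisect

        for lo, hi in zip(points, points[1:]):
            seg_start, seg_end = lo, hi - 1
            # covered iff some interval starts <= seg_start and ends >= seg_end
            n_started = bisect.bisect_right(starts, seg_start)
            n_ended = bisect.bisect_left(ends, seg_start)
            if n_started - n_ended > 0:
                out.append(GenomicInterval(chrom, seg_start, seg_end, strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
    return out


def assign_gene(
    cluster: TssCluster,
    gene_models: Sequence[GeneModel],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    point: str = "dominant",
) -> str | None:
    """Assign a cluster to the same-strand gene containing its reference point.

    The reference point (dominant position for on-site data, weighted center
    for near-site) must fall within the gene span extended upstream by
    ``promoter_window`` bp.  Ties between overlapping genes are broken by the
    nearest annotated transcript start.
    """
    pos = cluster.dominant_pos if point == "dominant" else cluster.center
    candidates: list[tuple[int, str]] = []
    for gene in gene_models:
        if gene.chrom != cluster.chrom or gene.strand != cluster.strand:
            continue
        span = gene.span
        if gene.strand == "+":
            lo, hi = span.start - promoter_window, span.end
        else:
            lo, hi = span.start, span.end + promoter_window
        if lo <= pos <= hi:
            nearest = min(abs(pos - t) for t in gene.tss_positions)
            candidates.append((nearest, gene.gene_id))
    if not candidates:
        return None
    return min(candidates)[1]


def assign_genes(
    clusters: Sequence[TssCluster],
    gene_models: Sequence[GeneModel],
    promoter_window: int = DEFAULT_PROMOTER_WINDOW,
    point: str = "dominant",
) -> None:
    """Assign all clusters in place."""
    for c in clusters:
        c.gene_id = assign_gene(c, gene_models, promoter_window, point)


# ---------------------------------------------------------------------------
# Serialization: BED6 plus total_count, dominant_pos, gene_id columns
# ---------------------------------------------------------------------------


def write_clusters_bed(clusters: Sequence[TssCluster], path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            iv = c.interval
            name = f"cluster_{i}"
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\t{c.total_count}"
                f"\t{iv.strand}\t{c.total_count}\t{c.dominant_pos}"
                f"\t{c.gene_id or '.'}\n"
            )


def read_clusters_bed(path, sample_id: str | None = None) -> list[TssCluster]:
    """Read clusters written by :func:`write_clusters_bed`.

    Per-position counts are not stored in BED; they are reconstructed as the
    total count placed at the dominant position (sufficient for centers and
    dominant positions of width-1 summaries; full position detail requires
    re-clustering from the mapped-TSS table).
    """
    clusters = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            iv = GenomicInterval(f[0], int(f[1]) + 1, int(f[2]), f[5])
            total = int(f[6]) if len(f) > 6 else int(f[4])
            dom = int(f[7]) if len(f) > 7 else iv.start
            gene = None if len(f) <= 8 or f[8] == "." else f[8]
            clusters.append(
                TssCluster(iv, {dom: total}, gene_id=gene, sample_id=sample_id)
            )
    return clusters


def write_intervals_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\tunified_{i}\t0\t{iv.strand}\n"
            )


def read_intervals_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(GenomicInterval(f[0], int(f[1]) + 1, int(f[2]), f[5]))
    return out
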