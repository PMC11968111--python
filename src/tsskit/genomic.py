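"""Core genomic data types, coordinate conventions and annotation handling.

Coordinates are 1-based, fully closed (GTF convention) everywhere inside the
package; BED input/output converts to and from 0-based half-open at the
boundary.  Transcript coordinates are 1-based along the spliced transcript in
5'->3' orientation, so position 1 is the transcript's TSS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = ("five_prime_most_exon", "other_exon", "intron", "intergenic")


class MappedTssTableError(ValueError):
    """Raised when a mapped-TSS table row cannot be parsed."""


@dataclass(frozen=True)
class MappedTssRecord:
    """One strand-aware genomic position with a read (UMI) count.

    The atomic unit of 5'-end evidence: the genomic base where the 5' end of
    a read maps, how many deduplicated reads support it, and optionally the
    cell barcode they came from (``None`` for bulk-level tables).
    """

    chrom: str
    pos: int
    count: int
    strand: str
    barcode: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 1-based and closed on both ends."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class Transcript:
    """A spliced transcript: exons sorted 5'->3' in transcript orientation."""

    tx_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        strand = self.exons[0].strand
        if any(e.strand != strand for e in self.exons):
            raise ValueError("all exons of a transcript must share a strand")
        key = [e.start for e in self.exons]
        ordered = sorted(key) if strand == "+" else sorted(key, reverse=True)
        if key != ordered:
            # normalise to transcript orientation
            self.exons = sorted(
                self.exons, key=lambda e: e.start, reverse=strand == "-"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if a.overlaps(b):
                raise ValueError("exons within a transcript must not overlap")

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def length(self) -> int:
        return sum(e.width for e in self.exons)

    @property
    def tss(self) -> int:
        """Genomic position of the transcript's 5'-most base."""
        first = self.exons[0]
        return first.start if self.strand == "+" else first.end

    def genomic_to_transcript(self, pos: int) -> int | None:
        """1-based transcript coordinate of ``pos``, or None if intronic."""
        offset = 0
        for exon in self.exons:
            if exon.contains(pos):
                if self.strand == "+":
                    return offset + (pos - exon.start) + 1
                return offset + (exon.end - pos) + 1
            offset += exon.width
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 1 <= tpos <= self.length:
            raise ValueError(
                f"transcript position {tpos} outside [1, {self.length}]"
            )
        offset = 0
        for exon in self.exons:
            if tpos <= offset + exon.width:
                within = tpos - offset - 1
                if self.strand == "+":
                    return exon.start + within
                return exon.end - within
            offset += exon.width
        raise AssertionError("unreachable")


@dataclass
class GeneModel:
    """A gene with its transcripts and their annotated start positions."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        starts = [e.start for t in self.transcripts for e in t.exons]
        ends = [e.end for t in self.transcripts for e in t.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)

    @property
    def tss_positions(self) -> list[int]:
        """5'-most position of each transcript (duplicates removed)."""
        seen: list[int] = []
        for t in self.transcripts:
            if t.tss not in seen:
                seen.append(t.tss)
        return seen

    def five_prime_most_exons(self) -> list[GenomicInterval]:
        return [t.exons[0] for t in self.transcripts]

    def contains_exonic(self, pos: int) -> bool:
        return any(
            e.contains(pos) for t in self.transcripts for e in t.exons
        )


@dataclass
class TssAnnotation:
    """Reference TSS positions: (gene_id, chrom, pos, strand) entries."""

    entries: list[tuple[str, str, int, str]]

    def by_gene(self) -> dict[str, list[tuple[str, int, str]]]:
        out: dict[str, list[tuple[str, int, str]]] = {}
        for gene_id, chrom, pos, strand in self.entries:
            out.setdefault(gene_id, []).append((chrom, pos, strand))
        return out

    def single_tss_genes(self) -> dict[str, tuple[str, int, str]]:
        """Genes with exactly one annotated TSS."""
        grouped = self.by_gene()
        return {g: v[0] for g, v in grouped.items() if len(v) == 1}


# ---------------------------------------------------------------------------
# Mapped-TSS tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("chrom", "pos", "count", "strand", "barcode")


def read_mapped_tss_table(path) -> list[MappedTssRecord]:
    """Read a mapped-TSS table (TSV: chrom, pos, count, strand[, barcode]).

    Rows with identical (chrom, pos, strand, barcode) are summed.  An
    optional header line is detected by a non-integer second column.
    """
    aggregated: dict[tuple, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) not in (4, 5):
                raise MappedTssTableError(
                    f"{path}: line {lineno}: expected 4 or 5 tab-separated "
                    f"columns, got {len(fields)}"
                )
            if lineno == 1 and not _is_int(fields[1]):
                continue  # header
            if not _is_int(fields[1]) or not _is_int(fields[2]):
                raise MappedTssTableError(
                    f"{path}: line {lineno}: non-integer position or count"
                )
            if fields[3] not in ("+", "-"):
                raise MappedTssTableError(
                    f"{path}: line {lineno}: strand must be '+' or '-', "
                    f"got {fields[3]!r}"
                )
            barcode = fields[4] if len(fields) == 5 else None
            key = (fields[0], int(fields[1]), fields[3], barcode)
            aggregated[key] = aggregated.get(key, 0) + int(fields[2])
    return [
        MappedTssRecord(chrom, pos, count, strand, barcode)
        for (chrom, pos, strand, barcode), count in sorted(
            aggregated.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
        )
    ]


def write_mapped_tss_table(records: Iterable[MappedTssRecord], path) -> None:
    """Write records as a mapped-TSS TSV (5th column only if barcoded)."""
    records = list(records)
    barcoded = any(r.barcode is not None for r in records)
    with open(path, "w") as fh:
        for r in records:
            row = [r.chrom, str(r.pos), str(r.count), r.strand]
            if barcoded:
                row.append(r.barcode or "")
            fh.write("\t".join(row) + "\n")


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Alignment-derived mapped TSS extraction
# ---------------------------------------------------------------------------


def extract_mapped_tss(
    alignments,
    read_end_policy: str = "read1_onsite",
    cell_tag: str = "CB",
    umi_tag: str = "UB",
) -> list[MappedTssRecord]:
    """Extract 5'-end records from aligned segments (e.g. a pysam iterator).

    ``read1_onsite`` keeps Read 1 (or unpaired reads); ``read2_nearsite``
    keeps Read 2.  The 5' end is the leftmost aligned base on '+' and the
    rightmost on '-'.  When UMI tags are present, one count per distinct UMI
    per (position, strand, barcode); otherwise raw read counts.  Unmapped,
    secondary and supplementary alignments are skipped and tallied.
    """
    if read_end_policy not in ("read1_onsite", "read2_nearsite"):
        raise ValueError(f"unknown read_end_policy {read_end_policy!r}")
    skipped = 0
    counts: dict[tuple, int] = {}
    umis: dict[tuple, set] = {}
    for aln in alignments:
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            skipped += 1
            continue
        if read_end_policy == "read1_onsite":
            if aln.is_paired and not aln.is_read1:
                continue
        else:
            if not aln.is_read2:
                continue
        strand = "-" if aln.is_reverse else "+"
        # reference_end is exclusive, so it is the 1-based rightmost base
        pos = aln.reference_end if aln.is_reverse else aln.reference_start + 1
        barcode = _get_tag(aln, cell_tag)
        umi = _get_tag(aln, umi_tag)
        key = (aln.reference_name, pos, strand, barcode)
        if umi is not None:
            umis.setdefault(key, set()).add(umi)
        else:
            counts[key] = counts.get(key, 0) + 1
    for key, u in umis.items():
        counts[key] = counts.get(key, 0) + len(u)
    if skipped:
        logger.info("extract_mapped_tss: skipped %d alignments", skipped)
    return [
        MappedTssRecord(chrom, pos, n, strand, barcode)
        for (chrom, pos, strand, barcode), n in sorted(
            counts.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
        )
    ]


def _get_tag(aln, tag: str):
    try:
        return aln.get_tag(tag)
    except KeyError:
        return None


# ---------------------------------------------------------------------------
# Position classification
# ---------------------------------------------------------------------------


def classify_position(
    pos: int, strand: str, chrom: str, gene_models: Sequence[GeneModel]
) -> str:
    """Classify a genomic position against same-strand gene models.

    Returns one of ``five_prime_most_exon``, ``other_exon``, ``intron`` or
    ``intergenic``.  Only genes on the same strand are considered; a position
    overlapping only an opposite-strand gene is intergenic.
    """
    in_other_exon = False
    in_span = False
    for gene in gene_models:
        if gene.chrom != chrom or gene.strand != strand:
            continue
        span = gene.span
        if not span.contains(pos):
            continue
        in_span = True
        for t in gene.transcripts:
            for i, exon in enumerate(t.exons):
                if exon.contains(pos):
                    if i == 0:
                        return "five_prime_most_exon"
                    in_other_exon = True
    if in_other_exon:
        return "other_exon"
    if in_span:
        return "intron"
    return "intergenic"


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def load_gene_models(path) -> list[GeneModel]:
    """Load gene models from GTF (via pyranges) or BED12."""
    path = str(path)
    if path.endswith((".bed", ".bed12")):
        return _load_bed12(path)
    import pyranges as pr

    df = pr.read_gtf(path).df
    exons = df[df.Feature == "exon"]
    genes: dict[str, GeneModel] = {}
    for (gene_id, tx_id), grp in exons.groupby(
        ["gene_id", "transcript_id"], sort=False
    ):
        chrom = str(grp.Chromosome.iloc[0])
        strand = str(grp.Strand.iloc[0])
        # pyranges converts GTF to 0-based half-open; convert back
        ivs = [
            GenomicInterval(chrom, int(s) + 1, int(e), strand)
            for s, e in zip(grp.Start, grp.End)
        ]
        tx = Transcript(str(tx_id), ivs)
        gene = genes.setdefault(str(gene_id), GeneModel(str(gene_id), chrom, strand))
        gene.transcripts.append(tx)
    return list(genes.values())


def _load_bed12(path) -> list[GeneModel]:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count",
        "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    genes: dict[str, GeneModel] = {}
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
        offs = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
        ivs = [
            GenomicInterval(
                row.chrom, row.start + off + 1, row.start + off + size, row.strand
            )
            for size, off in zip(sizes, offs)
        ]
        name = str(row.name)
        gene_id = name.split(".")[0] if "." in name else name
        tx = Transcript(name, ivs)
        gene = genes.setdefault(
            gene_id, GeneModel(gene_id, row.chrom, row.strand)
        )
        gene.transcripts.append(tx)
    return list(genes.values())


def read_tss_bed(path) -> TssAnnotation:
    """Read a TSS annotation BED (chrom, start, end, gene_id, score, strand).

    The TSS position is the 1-based start of the (1 bp) BED interval.
    """
    entries = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            entries.append((f[3], f[0], int(f[1]) + 1, f[5]))
    return TssAnnotation(entries)


def write_tss_bed(annotation: TssAnnotation, path) -> None:
    with open(path, "w") as fh:
        for gene_id, chrom, pos, strand in annotation.entries:
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{gene_id}\t0\t{strand}\n")


def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as a minimal valid GTF."""
    with open(path, "w") as fh:
        for gene in genes:
            span = gene.span
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write(
                f"{gene.chrom}\ttsskit\tgene\t{span.start}\t{span.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for tx in gene.transcripts:
                tattrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.tx_id}";'
                tmin = min(e.start for e in tx.exons)
                tmax = max(e.end for e in tx.exons)
                fh.write(
                    f"{gene.chrom}\ttsskit\ttranscript\t{tmin}\t{tmax}\t.\t"
                    f"{gene.strand}\t.\t{tattrs}\n"
                )
                for i, exon in enumerate(tx.exons, start=1):
                    fh.write(
                        f"{gene.chrom}\ttsskit\texon\t{exon.start}\t{exon.end}"
                        f"\t.\t{gene.strand}\t.\t{tattrs} exon_number \"{i}\";\n"
                    )
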