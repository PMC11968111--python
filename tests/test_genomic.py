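import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsskit.genomic import (
    MappedTssRecord,
    MappedTssTableError,
    classify_position,
    extract_mapped_tss,
    load_gene_models,
    read_mapped_tss_table,
    read_tss_bed,
    write_gtf,
    write_mapped_tss_table,
    write_tss_bed,
)


class TestMappedTssTable:
    def test_basic_row_with_padding(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("chr1 \t 1000 \t 5 \t +\n")
        (rec,) = read_mapped_tss_table(p)
        assert rec == MappedTssRecord("chr1", 1000, 5, "+")

    def test_duplicate_rows_are_summed(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("chr1\t1000\t2\t+\nchr1\t1000\t3\t+\n")
        (rec,) = read_mapped_tss_table(p)
        assert rec.count == 5

    def test_header_is_skipped(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("chrom\tpos\tcount\tstrand\nchr1\t10\t1\t-\n")
        (rec,) = read_mapped_tss_table(p)
        assert rec.strand == "-"

    @pytest.mark.parametrize(
        "row", ["chr1\t1000\tx\t+", "chr1\tabc\t5\t+", "chr1\t1000\t5\t*",
                "chr1\t1000\t5"]
    )
    def test_malformed_row_raises_with_line_number(self, tmp_path, row):
        p = tmp_path / "t.tsv"
        p.write_text("chr1\t5\t1\t+\n" + row + "\n")
        with pytest.raises(MappedTssTableError, match="line 2"):
            read_mapped_tss_table(p)

    def test_barcode_column_round_trip(self, tmp_path):
        p = tmp_path / "t.tsv"
        recs = [
            MappedTssRecord("chr1", 10, 2, "+", "BC1"),
            MappedTssRecord("chr1", 10, 3, "+", "BC2"),
        ]
        write_mapped_tss_table(recs, p)
        assert sorted(read_mapped_tss_table(p), key=lambda r: r.barcode) == recs

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(1, 10_000),
                st.integers(1, 50),
                st.sampled_from(["+", "-"]),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_preserves_count_multiset(self, tmp_path_factory, rows):
        tmp = tmp_path_factory.mktemp("rt") / "t.tsv"
        recs = [MappedTssRecord(*r) for r in rows]
        write_mapped_tss_table(recs, tmp)
        back = read_mapped_tss_table(tmp)
        want = {}
        for c, p, n, s in rows:
            want[(c, p, s)] = want.get((c, p, s), 0) + n
        got = {(r.chrom, r.pos, r.strand): r.count for r in back}
        assert got == want


class TestRecordInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(pos=0), dict(count=-1), dict(strand="*")],
    )
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(chrom="chr1", pos=1, count=1, strand="+")
        base.update(kwargs)
        with pytest.raises(ValueError):
            MappedTssRecord(**base)


def _make_bam(path, reads):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"LN": 100_000, "SN": "chr1"}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, flag, start, tags in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = start  # 0-based
            a.mapping_quality = 60
            a.cigarstring = "91M"
            a.query_sequence = "A" * 91
            for t, v in tags:
                a.set_tag(t, v)
            out.write(a)


class TestExtraction:
    def test_five_prime_end_by_strand(self, tmp_path):
        sam = tmp_path / "t.sam"
        # spans 1000-1090 (1-based): 0-based start 999
        _make_bam(sam, [("f", 0, 999, []), ("r", 16, 999, [])])
        recs = extract_mapped_tss(pysam.AlignmentFile(str(sam)))
        by_strand = {r.strand: r.pos for r in recs}
        assert by_strand == {"+": 1000, "-": 1090}

    def test_umi_dedup_and_cell_tags(self, tmp_path):
        sam = tmp_path / "t.sam"
        tags = [("CB", "BC1"), ("UB", "U1")]
        _make_bam(sam, [("a", 0, 999, tags), ("b", 0, 999, tags),
                        ("c", 0, 999, [("CB", "BC1"), ("UB", "U2")])])
        (rec,) = extract_mapped_tss(pysam.AlignmentFile(str(sam)))
        assert rec.count == 2 and rec.barcode == "BC1"

    def test_secondary_and_unmapped_skipped(self, tmp_path):
        sam = tmp_path / "t.sam"
        _make_bam(sam, [("a", 0, 999, []), ("b", 256, 999, []),
                        ("c", 4, 999, [])])
        recs = extract_mapped_tss(pysam.AlignmentFile(str(sam)))
        assert sum(r.count for r in recs) == 1

    def test_read2_policy_selects_read2(self, tmp_path):
        sam = tmp_path / "t.sam"
        # paired: read1 flag 0x1|0x40=65, read2 flag 0x1|0x80=129
        _make_bam(sam, [("p", 65, 999, []), ("p", 129, 1999, [])])
        recs = extract_mapped_tss(
            pysam.AlignmentFile(str(sam)), read_end_policy="read2_nearsite"
        )
        assert [r.pos for r in recs] == [2000]


class TestClassification:
    @pytest.mark.parametrize(
        "pos,strand,expected",
        [
            (10_050, "+", "five_prime_most_exon"),
            (20_050, "+", "other_exon"),
            (15_000, "+", "intron"),
            (40_000, "+", "intergenic"),
            (50_100, "-", "five_prime_most_exon"),
            (49_100, "-", "other_exon"),
            (49_500, "-", "intron"),
            (49_100, "+", "intergenic"),  # opposite strand only
        ],
    )
    def test_categories(self, gene_models, pos, strand, expected):
        assert classify_position(pos, strand, "chr1", gene_models) == expected

    def test_every_position_has_exactly_one_category(self, gene_models, rng):
        for pos in rng.integers(1, 100_000, 200):
            cat = classify_position(int(pos), "+", "chr1", gene_models)
            assert cat in (
                "five_prime_most_exon", "other_exon", "intron", "intergenic"
            )


class TestAnnotationIO:
    def test_gtf_round_trip(self, tmp_path, gene_models):
        path = tmp_path / "g.gtf"
        write_gtf(gene_models, path)
        back = load_gene_models(path)
        assert sorted(g.gene_id for g in back) == ["GA", "GB", "GC"]
        ga = next(g for g in back if g.gene_id == "GA")
        assert [
            (e.start, e.end) for e in ga.transcripts[0].exons
        ] == [(10_000, 10_100), (20_000, 20_200)]
        gb = next(g for g in back if g.gene_id == "GB")
        # minus-strand exons in transcript orientation: 5'-most first
        assert gb.transcripts[0].exons[0].start == 50_000
        assert gb.transcripts[0].tss == 50_300

    def test_tss_bed_round_trip(self, tmp_path):
        from tsskit.genomic import TssAnnotation

        ann = TssAnnotation([("G1", "chr1", 1000, "+"), ("G2", "chr2", 5, "-")])
        path = tmp_path / "t.bed"
        write_tss_bed(ann, path)
        assert read_tss_bed(path).entries == ann.entries


class TestTranscriptCoordinates:
    def test_projection_round_trip(self, two_exon_gene):
        tx = two_exon_gene.transcripts[0]
        assert tx.length == 101 + 201
        for tpos in (1, 101, 102, 302):
            assert tx.genomic_to_transcript(tx.transcript_to_genomic(tpos)) == tpos

    def test_intronic_position_has_no_transcript_coordinate(self, two_exon_gene):
        assert two_exon_gene.transcripts[0].genomic_to_transcript(15_000) is None

    def test_minus_strand_orientation(self, gene_models):
        gb = gene_models[1]
        tx = gb.transcripts[0]
        assert tx.genomic_to_transcript(50_300) == 1
        assert tx.genomic_to_transcript(49_200) == 302
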