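import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imprintcall.counts_io import (
    AlleleCount,
    PileupSite,
    filter_base_quality,
    library_stats,
    read_annotation,
    read_counts,
    read_mpileup,
    strand_from_orientation,
    write_counts,
)
from imprintcall.errors import ParseError, UndefinedStatisticError, ValidationError

HEADER = "chrom\tpos\tref\talt\tref_count\talt_count\tplus_count\tminus_count\n"


def _write(tmp_path, body, name="counts.tsv"):
    p = tmp_path / name
    p.write_text(HEADER + body)
    return p


class TestReadCounts:
    def test_empty_file_with_header(self, tmp_path):
        assert read_counts(_write(tmp_path, ""), "JXO") == []

    def test_rows_returned_sorted_by_position(self, tmp_path):
        p = _write(tmp_path, "chr1\t200\tA\tG\t5\t5\t10\t0\nchr1\t100\tC\tT\t3\t7\t10\t0\n")
        recs = read_counts(p, "JXO")
        assert [r.pos for r in recs] == [100, 200]
        assert all(r.cross_id == "JXO" for r in recs)

    def test_negative_count_rejected(self, tmp_path):
        p = _write(tmp_path, "chr1\t100\tA\tG\t5\t-1\t4\t0\n")
        with pytest.raises(ValidationError):
            read_counts(p, "JXO")

    def test_duplicate_site_rejected(self, tmp_path):
        body = "chr1\t100\tA\tG\t5\t5\t10\t0\nchr1\t100\tA\tG\t1\t1\t2\t0\n"
        with pytest.raises(ValidationError, match="duplicate"):
            read_counts(_write(tmp_path, body), "JXO")

    def test_malformed_line_names_line_number(self, tmp_path):
        p = _write(tmp_path, "chr1\t100\tA\tG\t5\tfive\t10\t0\n")
        with pytest.raises(ParseError, match=":2"):
            read_counts(p, "JXO")

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tposition\n")
        with pytest.raises(ParseError):
            read_counts(p, "JXO")

    def test_round_trip(self, tmp_path):
        body = "chr1\t100\tA\tG\t3\t7\t10\t0\nchr2\t5\tC\tT\t0\t9\t1\t8\n"
        recs = read_counts(_write(tmp_path, body), "X")
        out = tmp_path / "out.tsv"
        write_counts(recs, out)
        assert read_counts(out, "X") == recs


class TestBaseQualityFilter:
    @staticmethod
    def site(observations):
        return PileupSite(chrom="chr1", pos=50, ref_base="A", observations=observations)

    def test_no_filtering_at_high_quality(self):
        obs = tuple([("G", 40, "+")] * 8 + [("A", 40, "+")] * 4)
        rec = filter_base_quality(self.site(obs))
        assert (rec.alt_count, rec.ref_count) == (8, 4)
        assert rec.alt_base == "G"

    def test_low_quality_reads_dropped(self):
        # 12 reads, 5 at quality 12: only the 7 at >= 13 are counted
        obs = tuple([("G", 12, "+")] * 5 + [("G", 13, "+")] * 4 + [("A", 30, "-")] * 3)
        rec = filter_base_quality(self.site(obs))
        assert rec.coverage == 7
        assert (rec.alt_count, rec.ref_count) == (4, 3)

    def test_all_filtered_yields_zero_counts(self):
        obs = tuple([("G", 5, "+"), ("A", 12, "-")])
        rec = filter_base_quality(self.site(obs))
        assert (rec.ref_count, rec.alt_count) == (0, 0)
        assert rec.alt_base is None

    def test_third_alleles_tallied_separately(self):
        obs = tuple([("G", 40, "+")] * 5 + [("T", 40, "+")] * 2 + [("A", 40, "+")] * 3)
        rec = filter_base_quality(self.site(obs))
        assert rec.alt_base == "G"
        assert rec.other_count == 2
        assert rec.coverage == 8

    @settings(max_examples=50, deadline=None)
    @given(
        quals=st.lists(st.integers(min_value=0, max_value=60), min_size=1, max_size=40),
        q1=st.integers(min_value=0, max_value=60),
        q2=st.integers(min_value=0, max_value=60),
    )
    def test_monotone_in_quality_threshold(self, quals, q1, q2):
        """Raising the quality cutoff never increases any count."""
        lo, hi = min(q1, q2), max(q1, q2)
        obs = tuple(("G" if i % 3 else "A", q, "+") for i, q in enumerate(quals))
        rec_lo = filter_base_quality(self.site(obs), min_quality=lo)
        rec_hi = filter_base_quality(self.site(obs), min_quality=hi)
        assert rec_hi.ref_count <= rec_lo.ref_count
        assert rec_hi.coverage + rec_hi.other_count <= rec_lo.coverage + rec_lo.other_count


class TestMpileup:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "p.txt"
        # 3 ref (2 fwd, 1 rev), 2 alt G fwd; qualities all 'I' (40)
        p.write_text("chr1\t10\ta\t5\t..,GG\tIIIII\n")
        (rec,) = read_mpileup(p, "JXO")
        assert (rec.ref_count, rec.alt_count) == (3, 2)
        assert rec.alt_base == "G"
        assert (rec.plus_count, rec.minus_count) == (4, 1)

    def test_read_markers_and_indels_skipped(self, tmp_path):
        p = tmp_path / "p.txt"
        # ^F starts a read, $ ends one, +2AC is an insertion, * consumes a qual
        p.write_text("chr1\t10\tA\t6\t^F.$,+2ACg*.\tIIII!\n")
        (rec,) = read_mpileup(p, "JXO")
        # counted: '.', ',', 'g'; the last '.' got quality '!' (0) and is filtered
        assert (rec.ref_count, rec.alt_count) == (2, 1)

    def test_quality_offset_33(self, tmp_path):
        p = tmp_path / "p.txt"
        # '-' is phred 12 (below 13), '.'+33 -> '.' char ':' is 25
        p.write_text("chr1\t10\tA\t2\tGG\t-:\n")
        (rec,) = read_mpileup(p, "JXO")
        assert rec.alt_count == 1


class TestLibraryStats:
    @pytest.mark.parametrize(
        "total,aligned,expected",
        [(95_517_702, 76_712_608, 80.3), (117_618_284, 86_369_632, 73.4), (100, 100, 100.0)],
    )
    def test_aligned_percent_one_decimal(self, total, aligned, expected):
        assert library_stats(total, aligned).aligned_percent == expected

    def test_sense_fraction(self):
        s = library_stats(100, 100, 100)
        assert s.sense_percent == 100.0

    def test_zero_total_reads_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            library_stats(0, 0)

    def test_ordering_validated(self):
        with pytest.raises(ValidationError):
            library_stats(10, 20)


class TestStrandFromOrientation:
    @pytest.mark.parametrize(
        "code,strand",
        [("F2R1", "antisense"), ("R1F2", "antisense"), ("F1R2", "sense"), ("R2F1", "sense")],
    )
    def test_known_codes(self, code, strand):
        assert strand_from_orientation(code) == strand

    def test_unknown_code(self):
        with pytest.raises(ValidationError):
            strand_from_orientation("XYZ")


class TestAnnotationReaders:
    def test_bed6(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr12\t110779000\t110798000\tMeg3\t0\t+\n")
        (m,) = read_annotation(p)
        assert (m.transcript_id, m.strand, m.start, m.end) == ("Meg3", "+", 110779000, 110798000)

    def test_bed3_missing_strand(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        with pytest.raises(ValidationError, match="strand"):
            read_annotation(p)

    def test_bed12_blocks(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(
            "chr1\t100\t500\ttx1\t0\t-\t100\t500\t0\t2\t50,100,\t0,300,\n"
        )
        (m,) = read_annotation(p)
        assert m.exons == ((100, 150), (400, 500))

    def test_gtf_two_exons_grouped(self, tmp_path):
        p = tmp_path / "a.gtf"
        attrs = 'gene_id "g1"; transcript_id "tx1"; gene_name "Meg3";'
        p.write_text(
            f"chr1\ttest\texon\t101\t200\t.\t+\t.\t{attrs}\n"
            f"chr1\ttest\texon\t301\t400\t.\t+\t.\t{attrs}\n"
        )
        (m,) = read_annotation(p)
        assert m.transcript_id == "tx1"
        assert m.gene_name == "Meg3"
        assert m.exons == ((100, 200), (300, 400))
        assert (m.start, m.end) == (100, 400)


class TestAlleleCountInvariants:
    def test_strand_partition_enforced(self):
        with pytest.raises(ValidationError):
            AlleleCount("chr1", 10, "A", "G", 5, 5, 3, 3)

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValidationError):
            AlleleCount("chr1", 10, "A", "A", 5, 5)
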