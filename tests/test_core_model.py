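import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editscan.core_model import (
    BedRecordError,
    EditingMatrix,
    EditingSite,
    ExonRecord,
    GenomeReference,
    ReadAlignment,
    VariantCall,
    VcfParseError,
    blocks_from_cigar,
    parse_catalog_records,
    parse_interval_records,
    parse_site_key,
    parse_variant_records,
    write_variant_records,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def vcf_line(chrom="chr1", pos=100, ref="A", alt="G", dp=20, ad=5):
    rd = dp - ad
    return (f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\t"
            f"GT:DP:RD:AD:FREQ\t0/1:{dp}:{rd}:{ad}:{ad / dp * 100:.2f}%\n")


class TestParseVariantRecords:
    def test_pos_conversion_and_af(self):
        res = parse_variant_records(io.StringIO(VCF_HEADER + vcf_line()))
        (call,) = res.calls
        assert call.pos0 == 99
        assert call.allele_frequency == pytest.approx(0.25)

    def test_multiallelic_split(self):
        line = "chr1\t100\t.\tA\tG,T\t.\t.\tDP4=10,5,3,2\n"
        res = parse_variant_records(io.StringIO(VCF_HEADER + line))
        assert len(res.calls) == 2
        assert {c.alt_base for c in res.calls} == {"G", "T"}
        assert all(c.pos0 == 99 for c in res.calls)

    def test_indel_skipped_with_counter(self):
        line = "chr1\t100\t.\tAT\tA\t.\t.\t.\tGT:DP:RD:AD\t0/1:20:15:5\n"
        res = parse_variant_records(io.StringIO(VCF_HEADER + line))
        assert res.calls == []
        assert res.skipped_non_snv == 1

    def test_malformed_line_names_line_number(self):
        bad = VCF_HEADER + vcf_line() + "chr1\tnotanint\t.\tA\tG\t.\t.\t.\n"
        with pytest.raises(VcfParseError, match="line 4"):
            parse_variant_records(io.StringIO(bad))

    def test_missing_depth_skip_vs_fail(self):
        from editscan.core_model import VcfDialect
        line = "chr1\t100\t.\tA\tG\t.\t.\t.\n"
        res = parse_variant_records(io.StringIO(VCF_HEADER + line))
        assert res.skipped_no_depth == 1
        with pytest.raises(VcfParseError):
            parse_variant_records(
                io.StringIO(VCF_HEADER + line),
                dialect=VcfDialect(on_missing_depth="fail"))

    def test_round_trip_randomized(self):
        rng = np.random.default_rng(5)
        bases = "ACGT"
        calls = []
        for i in range(1000):
            ref, alt = rng.choice(list(bases), size=2, replace=False)
            dp = int(rng.integers(1, 500))
            ad = int(rng.integers(0, dp + 1))
            calls.append(VariantCall("chr%d" % rng.integers(1, 4),
                                     int(rng.integers(0, 10_000)),
                                     ref, alt, dp, ad, sample_id="S1"))
        buf = io.StringIO()
        write_variant_records(buf, calls, sample_id="S1")
        buf.seek(0)
        parsed = parse_variant_records(buf, sample_id="S1").calls
        assert len(parsed) == len(calls)
        for a, b in zip(calls, parsed):
            assert (a.chrom, a.pos0, a.ref_base, a.alt_base,
                    a.total_depth, a.alt_depth) == \
                   (b.chrom, b.pos0, b.ref_base, b.alt_base,
                    b.total_depth, b.alt_depth)


class TestBed:
    def test_full_record(self):
        recs = parse_interval_records(
            io.StringIO("chr1\t10\t20\tseedA\t0\t+\n"))
        assert recs[0] == ("chr1", 10, 20, "seedA", "+")

    def test_defaults(self):
        recs = parse_interval_records(io.StringIO("chr2\t5\t6\n"))
        assert recs[0].name == "." and recs[0].strand == "+"

    def test_empty_interval_is_error(self):
        with pytest.raises(BedRecordError):
            parse_interval_records(io.StringIO("chr2\t9\t9\n"))

    def test_interval_length_convention(self):
        recs = parse_interval_records(io.StringIO("chr1\t100\t250\n"))
        assert recs[0].end0 - recs[0].start0 == 150


class TestCatalog:
    def test_position_conversion(self):
        text = "chrom\tposition\tgene\tregion\tstrand\n" \
               "chr12\t69237005\tMDM2\t3'UTR\t+\n"
        (site,) = parse_catalog_records(io.StringIO(text))
        assert site.pos0 == 69237004
        assert site.region == "3UTR"
        assert site.gene == "MDM2"

    def test_case_normalization(self):
        text = "h\np\ng\nr\ns\n".replace("\n", "\t") + "\n" \
               + "chr1\t100\tX\t3utr\t+\n"
        (site,) = parse_catalog_records(io.StringIO(text))
        assert site.region == "3UTR"

    def test_minus_strand_complemented(self):
        text = "h\tp\tg\tr\ts\nchr1\t100\tX\tintron\t-\n"
        (site,) = parse_catalog_records(io.StringIO(text))
        assert (site.ref_base, site.alt_base, site.strand) == ("T", "C", "-")

    def test_unknown_region_warns_to_unknown(self):
        text = "h\tp\tg\tr\ts\nchr1\t100\tX\tweird\t+\n"
        (site,) = parse_catalog_records(io.StringIO(text))
        assert site.region == "unknown"


class TestCigarBlocks:
    def test_simple_match(self):
        assert blocks_from_cigar([(0, 30)], 10, 30) == ((10, 40, 0, 30),)

    def test_intron_consumes_reference_only(self):
        blocks = blocks_from_cigar([(0, 10), (3, 50), (0, 10)], 0, 20)
        assert blocks == ((0, 10, 0, 10), (60, 70, 10, 20))

    def test_insertion_and_softclip(self):
        # 5S10M2I10M: soft clip + insertion consume query only
        blocks = blocks_from_cigar([(4, 5), (0, 10), (1, 2), (0, 10)], 100, 27)
        assert blocks == ((100, 110, 5, 15), (110, 120, 17, 27))

    @given(st.lists(st.tuples(st.sampled_from([0, 1, 2, 3, 4]),
                              st.integers(1, 20)),
                    min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_query_span_matches_cigar(self, cigar):
        # property: sum of block query spans == aligned query bases (M ops)
        query_len = sum(length for op, length in cigar if op in (0, 1, 4))
        aligned = sum(length for op, length in cigar if op == 0)
        if aligned == 0:
            return
        blocks = blocks_from_cigar(cigar, 0, query_len)
        assert sum(q1 - q0 for _, _, q0, q1 in blocks) == aligned
        assert sum(r1 - r0 for r0, r1, _, _ in blocks) == aligned


class TestTypes:
    def test_genome_rejects_bad_chars(self):
        with pytest.raises(ValueError):
            GenomeReference({"chr1": "ACGTX"})

    def test_variant_invariants(self):
        with pytest.raises(ValueError):
            VariantCall("chr1", 0, "A", "A", 10, 5)
        with pytest.raises(ValueError):
            VariantCall("chr1", 0, "A", "G", 10, 11)

    def test_exon_record_requires_intron(self):
        with pytest.raises(ValueError):
            ExonRecord("chr1", "+", ((0, 10), (10, 20)), "tx")

    def test_read_query_base_at_gap_is_none(self):
        read = ReadAlignment("r", "chr1", 0,
                             ((0, 5, 0, 5), (8, 13, 5, 10)),
                             "+", "ACGTACGTAC")
        assert read.query_base_at(6) is None
        assert read.query_base_at(2) == "G"  # query[2]
        assert read.query_base_at(8) == "C"  # second block: query[5]

    def test_site_key_round_trip(self):
        site = EditingSite("chr5", 1234, ref_base="A", alt_base="G")
        assert parse_site_key(site.key) == ("chr5", 1234, "A", "G")


class TestEditingMatrix:
    def test_tsv_round_trip(self):
        m = EditingMatrix.empty(["chr1:5:A>G", "chr1:9:A>G"], ["s1", "s2"])
        m.set_cell(0, 0, 30, 0.25)
        m.set_cell(1, 1, 12, 0.0)
        text = m.to_string()
        back = EditingMatrix.from_tsv(io.StringIO(text))
        assert back.site_keys == m.site_keys
        assert back.samples == m.samples
        assert np.array_equal(back.depth, m.depth)
        assert back.missing[0, 1] and back.missing[1, 0]
        assert back.level[0, 0] == pytest.approx(0.25)

    def test_rejects_negative_depth(self):
        with pytest.raises(ValueError):
            EditingMatrix(["k"], ["s"], np.array([[-5]]), np.array([[0.1]]))
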