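import math

import pytest

from editscan.core_model.types import (
    ExonAnnotation,
    ExonRecord,
    ReadAlignment,
    VariantCall,
)
from editscan.raar import (
    RaarConfig,
    RealignmentHit,
    ScoringScheme,
    adjudicate_variant,
    extract_supporting_reads,
    junction_proximity,
    select_best_alignment,
)
from editscan.raar.verdicts import (
    CONFIRM,
    REFUTE,
    STATUS_INDEL,
    STATUS_LOWSUPPORT,
    STATUS_MULTI,
    STATUS_PASS,
    STATUS_SPLICE,
    ReadVerdict,
)

VARIANT = VariantCall("chr1", 100, "A", "G", 20, 10)


def hit(start0, length=50, score=48.0, chrom="chr1", spliced=False,
        gapped=False, blocks=None):
    if blocks is None:
        blocks = ((start0, start0 + length, 0, length),)
    return RealignmentHit(chrom=chrom, start0=blocks[0][0],
                          end0=blocks[-1][1], strand="+", blocks=blocks,
                          score=score, identity=0.96, spliced=spliced,
                          gapped=gapped)


def read_with_alt(start0=80, length=50, alt_at=100, alt="G", seq=None):
    if seq is None:
        seq = list("A" * length)
        seq[alt_at - start0] = alt
        seq = "".join(seq)
    return ReadAlignment("r1", "chr1", start0,
                         ((start0, start0 + length, 0, length),), "+", seq)


class TestExtractSupportingReads:
    def test_no_coverage(self):
        read = read_with_alt(start0=300, seq="G" * 50)
        assert extract_supporting_reads(VARIANT, [read]) == []

    def test_only_alt_carriers(self):
        alt_read = read_with_alt()
        ref_read = ReadAlignment("r2", "chr1", 80,
                                 ((80, 130, 0, 50),), "+", "A" * 50)
        out = extract_supporting_reads(VARIANT, [alt_read, ref_read])
        assert [r.read_id for r in out] == ["r1"]

    def test_gap_coverage_excluded(self):
        # blocks 95-100 and 103-108: pos0=100 falls in the N gap
        read = ReadAlignment("r3", "chr1", 95,
                             ((95, 100, 0, 5), (103, 108, 5, 10)),
                             "+", "G" * 10)
        assert extract_supporting_reads(VARIANT, [read]) == []


class TestSelectBestAlignment:
    def setup_method(self):
        self.read = read_with_alt()

    def test_single_supporting_hit_confirms(self):
        v = select_best_alignment([hit(80)], VARIANT, self.read)
        assert (v.status, v.reason) == (CONFIRM, "ok")

    def test_best_elsewhere(self):
        hits = [hit(5000, score=20.0), hit(80, score=18.0)]
        v = select_best_alignment(hits, VARIANT, self.read)
        assert (v.status, v.reason) == (REFUTE, "best_elsewhere")

    def test_near_tie_boundary_inclusive(self):
        # off-locus 19 vs locus 20: 0.95 * 20 = 19 -> refute
        hits = [hit(80, score=20.0), hit(5000, score=19.0)]
        v = select_best_alignment(hits, VARIANT, self.read)
        assert (v.status, v.reason) == (REFUTE, "near_tie")

    def test_just_below_band_confirms(self):
        hits = [hit(80, score=20.0), hit(5000, score=18.9)]
        v = select_best_alignment(hits, VARIANT, self.read)
        assert v.status == CONFIRM

    def test_spliced_hit_erasing_variant(self):
        spliced = hit(60, score=47.0, spliced=True,
                      blocks=((60, 100, 0, 40), (220, 230, 40, 50)))
        v = select_best_alignment([spliced, hit(80, score=44.0)],
                                  VARIANT, self.read)
        assert (v.status, v.reason) == (REFUTE, "spliced_better")

    def test_gapped_hit_erasing_variant(self):
        gapped = hit(80, score=47.0, gapped=True,
                     blocks=((80, 100, 0, 20), (102, 132, 20, 50)))
        v = select_best_alignment([gapped, hit(80, score=30.0)],
                                  VARIANT, self.read)
        assert (v.status, v.reason) == (REFUTE, "gapped_better")

    def test_alt_lost(self):
        # top hit covers pos0 ungapped but the aligned base is not alt
        other = ReadAlignment("r9", "chr1", 80, ((80, 130, 0, 50),),
                              "+", "A" * 50)
        v = select_best_alignment([hit(80, score=50.0)], VARIANT, other)
        assert (v.status, v.reason) == (REFUTE, "alt_lost")

    def test_empty_hits_error(self):
        with pytest.raises(ValueError):
            select_best_alignment([], VARIANT, self.read)

    def test_near_tie_monotonic_in_ratio(self):
        # confirmed set is non-increasing as near_tie_ratio decreases
        hits = [hit(80, score=20.0), hit(5000, score=17.0)]
        confirmed = []
        for ratio in (1.0, 0.95, 0.9, 0.85, 0.8):
            scheme = ScoringScheme(near_tie_ratio=ratio)
            v = select_best_alignment(hits, VARIANT, self.read, scheme)
            confirmed.append(v.status == CONFIRM)
        # once refuted at some ratio, stays refuted for all smaller ratios
        assert confirmed == sorted(confirmed, reverse=True)


class TestAdjudicateVariant:
    def test_all_confirm_passes(self):
        verdicts = [ReadVerdict(f"r{i}", CONFIRM, "ok") for i in range(10)]
        out = adjudicate_variant(VARIANT, verdicts)
        assert out.status == STATUS_PASS
        assert out.confirmed_fraction == 1.0

    def test_half_refuted_multi(self):
        verdicts = [ReadVerdict(f"r{i}", CONFIRM, "ok") for i in range(5)] \
            + [ReadVerdict(f"q{i}", REFUTE, "best_elsewhere")
               for i in range(5)]
        assert adjudicate_variant(VARIANT, verdicts).status == STATUS_MULTI

    def test_modal_reason_mapping(self):
        verdicts = [ReadVerdict(f"r{i}", REFUTE, "spliced_better")
                    for i in range(6)]
        assert adjudicate_variant(VARIANT, verdicts).status == STATUS_SPLICE

    def test_reason_tie_breaks_multi_over_splice(self):
        verdicts = [ReadVerdict("a", REFUTE, "near_tie"),
                    ReadVerdict("b", REFUTE, "spliced_better")]
        assert adjudicate_variant(VARIANT, verdicts).status == STATUS_MULTI

    def test_indel_class(self):
        verdicts = [ReadVerdict(f"r{i}", REFUTE, "gapped_better")
                    for i in range(4)]
        assert adjudicate_variant(VARIANT, verdicts).status == STATUS_INDEL

    def test_zero_reads_low_support(self):
        out = adjudicate_variant(VARIANT, [])
        assert out.status == STATUS_LOWSUPPORT
        assert out.n_supporting == 0

    def test_confirmed_below_read_floor(self):
        verdicts = [ReadVerdict(f"r{i}", CONFIRM, "ok") for i in range(4)]
        assert adjudicate_variant(VARIANT, verdicts).status == STATUS_LOWSUPPORT

    def test_alt_lost_dominant_low_support(self):
        verdicts = [ReadVerdict(f"r{i}", REFUTE, "alt_lost")
                    for i in range(8)]
        assert adjudicate_variant(VARIANT, verdicts).status == STATUS_LOWSUPPORT


class TestJunctionProximity:
    ANN = ExonAnnotation([ExonRecord("chr1", "+", ((100, 500), (800, 1200)),
                                     "tx1")])

    def test_one_base_inside_exon_end(self):
        v = VariantCall("chr1", 499, "A", "G", 10, 5)
        assert junction_proximity(v, self.ANN) == 1

    def test_mid_exon(self):
        v = VariantCall("chr1", 300, "A", "G", 10, 5)
        assert junction_proximity(v, self.ANN) == 200

    def test_unannotated_chromosome_infinite(self):
        v = VariantCall("chrX", 300, "A", "G", 10, 5)
        assert junction_proximity(v, self.ANN) == math.inf
        assert junction_proximity(v, None) == math.inf
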