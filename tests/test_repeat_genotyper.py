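"""Indel normalization and microsatellite allele classification."""

import pytest

from chng3.formats_io import GenomicInterval, VariantRecord
from chng3.repeat_genotyper import (
    AlleleClass,
    ConsistencyError,
    RepeatLocus,
    apply_variant,
    call_repeat_allele,
    find_repeat_tract,
    genotype_sample,
    normalize_variant,
)


class TestNormalizeVariant:
    def test_all_equivalent_deletion_placements_normalize_identically(
        self, repeat_reference
    ):
        seq, locus, seq_start = repeat_reference
        t0 = locus.tract.start
        # delete one TTTG unit at each of the 4 in-tract offsets (plus the
        # anchored representation one base left of the tract)
        keys = set()
        for shift in range(4):
            pos = t0 - 1 + 4 * shift
            off = pos - seq_start
            v = VariantRecord(locus.chrom, pos, seq[off: off + 5], seq[off])
            keys.add(normalize_variant(seq, v, seq_start).key())
        assert len(keys) == 1

    def test_minimal_snv_unchanged(self, repeat_reference):
        seq, locus, seq_start = repeat_reference
        v = VariantRecord(locus.chrom, 88_569_448, "T", "C")
        assert normalize_variant(seq, v, seq_start) == v

    def test_homopolymer_representations_share_one_key(self):
        #      123456789...
        seq = "ACGTACTTTTTGACGTACGTACGTACGTAC"  # T-run at 7..11 then G
        # deleting one T: every anchored representation must normalize equally
        reps = [
            VariantRecord("x", 6, "CT", "C"),
            VariantRecord("x", 7, "TT", "T"),
            VariantRecord("x", 10, "TT", "T"),
            VariantRecord("x", 11, "TG", "G"),  # right-shifted style
        ]
        keys = {normalize_variant(seq, v).key() for v in reps}
        assert len(keys) == 1

    def test_ref_mismatch_raises(self, repeat_reference):
        seq, locus, seq_start = repeat_reference
        with pytest.raises(ConsistencyError):
            normalize_variant(
                seq, VariantRecord(locus.chrom, 88_569_448, "A", "C"), seq_start
            )


class TestFindRepeatTract:
    def test_perfect_tract_counted(self):
        seq = "AC" + "TTTG" * 4 + "CA"
        tract, count = find_repeat_tract(seq, "TTTG", anchor_pos=5)
        assert count == 4
        assert tract == (3, 18)

    def test_internal_snv_leaves_maximal_perfect_run(self):
        # third unit mutated TTTG -> TTCG: maximal perfect run is 2 (left) vs
        # 1 (right); the longest overlapping the left anchor has count 2
        seq = "AC" + "TTTG" * 2 + "TTCG" + "TTTG" + "CA"
        _, count = find_repeat_tract(seq, "TTTG", anchor_pos=3)
        assert count == 2

    def test_absent_unit_gives_zero(self):
        _, count = find_repeat_tract("ACACACACAC", "TTTG", anchor_pos=5)
        assert count == 0


class TestCallRepeatAllele:
    def test_printed_deletion_is_unit_loss_three(
        self, repeat_reference, printed_deletion
    ):
        seq, locus, seq_start = repeat_reference
        call = call_repeat_allele(locus, seq, printed_deletion, seq_start)
        assert call.allele_class is AlleleClass.UNIT_LOSS
        assert call.unit_count == 3

    def test_internal_snv_is_disrupting(self, repeat_reference, repeat_internal_snv):
        seq, locus, seq_start = repeat_reference
        call = call_repeat_allele(locus, seq, repeat_internal_snv, seq_start)
        assert call.allele_class is AlleleClass.SNV_DISRUPTED

    def test_one_unit_insertion_is_unit_gain_five(self, repeat_reference):
        seq, locus, seq_start = repeat_reference
        pos = locus.tract.start - 1
        anchor = seq[pos - seq_start]
        v = VariantRecord(locus.chrom, pos, anchor, anchor + "TTTG")
        call = call_repeat_allele(locus, seq, v, seq_start)
        assert call.allele_class is AlleleClass.UNIT_GAIN
        assert call.unit_count == 5

    def test_non_multiple_indel_is_other(self, repeat_reference):
        seq, locus, seq_start = repeat_reference
        pos = locus.tract.start - 1
        off = pos - seq_start
        v = VariantRecord(locus.chrom, pos, seq[off: off + 3], seq[off])
        call = call_repeat_allele(locus, seq, v, seq_start)
        assert call.allele_class is AlleleClass.OTHER

    def test_distant_variant_is_out_of_scope(self, repeat_reference):
        seq, locus, seq_start = repeat_reference
        pos = seq_start + 5  # deep in the left flank
        v = VariantRecord(locus.chrom, pos, seq[pos - seq_start], "A")
        if v.ref == "A":
            v = VariantRecord(locus.chrom, pos, v.ref, "C")
        call = call_repeat_allele(locus, seq, v, seq_start)
        assert call.allele_class is AlleleClass.OUT_OF_SCOPE

    def test_no_variant_is_ref(self, repeat_reference):
        seq, locus, seq_start = repeat_reference
        call = call_repeat_allele(locus, seq, None, seq_start)
        assert call.allele_class is AlleleClass.REF
        assert call.unit_count == 4

    def test_call_invariant_under_equivalent_placements(self, repeat_reference):
        seq, locus, seq_start = repeat_reference
        t0 = locus.tract.start
        calls = set()
        for shift in range(4):
            pos = t0 - 1 + 4 * shift
            off = pos - seq_start
            v = VariantRecord(locus.chrom, pos, seq[off: off + 5], seq[off])
            c = call_repeat_allele(locus, seq, v, seq_start)
            calls.add((c.allele_class, c.unit_count))
        assert calls == {(AlleleClass.UNIT_LOSS, 3)}

    def test_applying_then_reverting_restores_ref(
        self, repeat_reference, printed_deletion
    ):
        seq, locus, seq_start = repeat_reference
        v = normalize_variant(seq, printed_deletion, seq_start)
        alt_seq = apply_variant(seq, v, seq_start)
        back = apply_variant(
            alt_seq, VariantRecord(v.chrom, v.pos, v.alt, v.ref), seq_start
        )
        assert back == seq
        assert (
            call_repeat_allele(locus, seq, None, seq_start).allele_class
            is AlleleClass.REF
        )


class TestGenotypeSample:
    def test_no_variants_is_ref_ref(self, repeat_reference):
        seq, locus, seq_start = repeat_reference
        h1, h2 = genotype_sample(locus, seq, [], seq_start)
        assert (h1.allele_class, h2.allele_class) == (AlleleClass.REF, AlleleClass.REF)

    def test_heterozygous_deletion(self, repeat_reference, printed_deletion):
        seq, locus, seq_start = repeat_reference
        h1, h2 = genotype_sample(locus, seq, [(printed_deletion, 1)], seq_start)
        assert h1.allele_class is AlleleClass.REF
        assert h2.allele_class is AlleleClass.UNIT_LOSS
        assert h2.unit_count == 3

    def test_homozygous_deletion(self, repeat_reference, printed_deletion):
        seq, locus, seq_start = repeat_reference
        h1, h2 = genotype_sample(locus, seq, [(printed_deletion, 2)], seq_start)
        assert h1.allele_class is h2.allele_class is AlleleClass.UNIT_LOSS
        assert (h1.unit_count, h2.unit_count) == (3, 3)

    def test_two_unphased_variants_ambiguous(
        self, repeat_reference, printed_deletion, repeat_internal_snv
    ):
        seq, locus, seq_start = repeat_reference
        h1, h2 = genotype_sample(
            locus, seq, [(printed_deletion, 1), (repeat_internal_snv, 1)], seq_start
        )
        assert h1.allele_class is AlleleClass.AMBIGUOUS


def test_self_periodic_unit_rejected():
    from chng3.formats_io import ValidationError

    with pytest.raises(ValidationError, match="periodic"):
        RepeatLocus("chr1", GenomicInterval("chr1", 10, 17), unit="ATAT", ref_units=2)
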