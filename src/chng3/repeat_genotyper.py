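"""Deterministic microsatellite allele calling at a short-tandem-repeat locus.

The disease locus here is a (TTTG)4 microsatellite whose pathogenic alleles
are a one-unit contraction ((TTTG)3, printed as a 4-bp deletion) and a
repeat-internal single-base substitution. Indels inside a repeat tract have
many equivalent VCF representations, so every variant is first normalized
(parsimony + left alignment) to a single canonical key; the caller then
applies the variant to the reference sequence, re-locates the maximal
perfect repeat run, and classifies the allele.

All sequences are plus-strand. ``seq_start`` arguments give the 1-based
chromosomal coordinate of the first base of the supplied sequence string, so
printed GRCh38-style coordinates can be used against a synthetic reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .formats_io import GenomicInterval, ValidationError, VariantRecord


class AlleleClass(str, Enum):
    REF = "REF"
    UNIT_LOSS = "UNIT_LOSS"
    UNIT_GAIN = "UNIT_GAIN"
    SNV_DISRUPTED = "SNV_DISRUPTED"
    OTHER = "OTHER"
    OUT_OF_SCOPE = "OUT_OF_SCOPE"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class RepeatLocus:
    """Reference repeat tract: ``ref_units`` perfect copies of ``unit``."""

    chrom: str
    tract: GenomicInterval
    unit: str = "TTTG"
    ref_units: int = 4

    def __post_init__(self) -> None:
        if self.tract.length() != self.ref_units * len(self.unit):
            raise ValidationError(
                f"tract length {self.tract.length()} != "
                f"{self.ref_units} x {len(self.unit)}"
            )
        # self-periodic units (e.g. ATAT) make unit counts ambiguous
        u = self.unit
        for p in range(1, len(u)):
            if len(u) % p == 0 and u == u[: p] * (len(u) // p):
                raise ValidationError(f"unit {u!r} is self-periodic with period {p}")


@dataclass(frozen=True)
class RepeatCall:
    allele_class: AlleleClass
    unit_count: int | None = None
    disrupting_change: VariantRecord | None = None


class ConsistencyError(ValueError):
    """Variant REF allele disagrees with the supplied reference sequence."""


# ---------------------------------------------------------------------------
# Variant normalization
# ---------------------------------------------------------------------------

def normalize_variant(
    ref_seq: str, variant: VariantRecord, seq_start: int = 1
) -> VariantRecord:
    """Return the parsimonious, left-aligned representation of ``variant``.

    Shared suffixes then prefixes are trimmed to the minimal form (indels
    keep >= 1 base in both alleles); indels are then shifted left while the
    base preceding the variant equals the last base of the longer allele.
    SNVs already minimal come back unchanged.
    """
    off = variant.pos - seq_start
    if off < 0 or off + len(variant.ref) > len(ref_seq):
        raise ConsistencyError(
            f"variant {variant.chrom}:{variant.pos} outside supplied sequence"
        )
    if ref_seq[off: off + len(variant.ref)] != variant.ref:
        raise ConsistencyError(
            f"REF {variant.ref!r} != sequence "
            f"{ref_seq[off: off + len(variant.ref)]!r} at {variant.chrom}:{variant.pos}"
        )

    ref, alt, pos = variant.ref, variant.alt, variant.pos

    # trim shared suffix (keep at least one base each)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    if len(ref) != len(alt):
        # left-align: while the final bases agree, slide one base left
        while True:
            if ref[-1] == alt[-1] and pos - 1 >= seq_start:
                prev = ref_seq[pos - 1 - seq_start]
                ref, alt = prev + ref[:-1], prev + alt[:-1]
                pos -= 1
            else:
                break
        # re-trim prefix exposed by the shift
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1

    return VariantRecord(variant.chrom, pos, ref, alt, id=variant.id)


def apply_variant(ref_seq: str, variant: VariantRecord, seq_start: int = 1) -> str:
    """Substitute ALT for REF in the sequence (single haplotype)."""
    off = variant.pos - seq_start
    if ref_seq[off: off + len(variant.ref)] != variant.ref:
        raise ConsistencyError(f"REF mismatch at {variant.chrom}:{variant.pos}")
    return ref_seq[:off] + variant.alt + ref_seq[off + len(variant.ref):]


# ---------------------------------------------------------------------------
# Repeat-tract location
# ---------------------------------------------------------------------------

def find_repeat_tract(
    seq: str, unit: str, anchor_pos: int, seq_start: int = 1
) -> tuple[tuple[int, int] | None, int]:
    """Locate the maximal run of perfect ``unit`` copies overlapping an anchor.

    All phases are scanned; among runs whose 1-based span ``start..end``
    overlaps ``anchor_pos`` (or abuts it, for anchors at a run edge after an
    indel), the longest is chosen (leftmost on ties). Returns
    ``((start, end), unit_count)`` in chromosome coordinates, or
    ``(None, 0)`` when no copy of the unit overlaps the anchor.
    """
    u = len(unit)
    if not (seq_start <= anchor_pos <= seq_start + len(seq) - 1):
        raise ValidationError(f"anchor {anchor_pos} outside sequence")
    best: tuple[int, int] | None = None
    best_count = 0
    i = 0
    n = len(seq)
    while i + u <= n:
        if seq[i: i + u] == unit and (i < u or seq[i - u: i] != unit):
            # run start
            count = 1
            while seq[i + count * u: i + (count + 1) * u] == unit:
                count += 1
            start = seq_start + i
            end = start + count * u - 1
            if start - 1 <= anchor_pos <= end + 1 and count > best_count:
                best, best_count = (start, end), count
            i += count * u
        else:
            i += 1
    return best, best_count


# ---------------------------------------------------------------------------
# Allele classification
# ---------------------------------------------------------------------------

def call_repeat_allele(
    locus: RepeatLocus,
    ref_seq: str,
    variant: VariantRecord | None,
    seq_start: int = 1,
    flank_window: int = 50,
) -> RepeatCall:
    """Classify one haplotype's allele at the repeat locus.

    The (normalized) variant is applied to the reference; the maximal
    perfect repeat run is re-located on the alternate sequence and the
    allele classified:

    * pure length change by a multiple of the unit, confined to the tract ->
      ``UNIT_LOSS`` / ``UNIT_GAIN`` with the new unit count;
    * single-base substitution inside the tract (no length change) ->
      ``SNV_DISRUPTED``;
    * variant further than ``flank_window`` bases from the tract ->
      ``OUT_OF_SCOPE``;
    * anything else -> ``OTHER``.
    """
    if variant is None:
        return RepeatCall(AlleleClass.REF, unit_count=locus.ref_units)
    v = normalize_variant(ref_seq, variant, seq_start=seq_start)
    tract = locus.tract
    if (
        v.pos + len(v.ref) - 1 < tract.start - flank_window
        or v.pos > tract.end + flank_window
    ):
        return RepeatCall(AlleleClass.OUT_OF_SCOPE, disrupting_change=v)

    alt_seq = apply_variant(ref_seq, v, seq_start=seq_start)
    # anchor at the tract start, clamped into the altered sequence
    anchor = min(tract.start, seq_start + len(alt_seq) - 1)
    _, alt_count = find_repeat_tract(alt_seq, locus.unit, anchor, seq_start=seq_start)

    delta = len(v.alt) - len(v.ref)
    unit_len = len(locus.unit)
    within_tract = tract.start - unit_len <= v.pos <= tract.end
    if delta != 0 and delta % unit_len == 0 and within_tract:
        expected = locus.ref_units + delta // unit_len
        if alt_count == expected:
            cls = AlleleClass.UNIT_LOSS if delta < 0 else AlleleClass.UNIT_GAIN
            return RepeatCall(cls, unit_count=alt_count, disrupting_change=v)
    if delta == 0 and v.is_snv() and tract.contains(v.pos):
        return RepeatCall(
            AlleleClass.SNV_DISRUPTED, unit_count=alt_count, disrupting_change=v
        )
    if v.ref == v.alt:  # cannot happen (VariantRecord forbids), defensive
        return RepeatCall(AlleleClass.REF, unit_count=locus.ref_units)
    return RepeatCall(AlleleClass.OTHER, unit_count=alt_count, disrupting_change=v)


def genotype_sample(
    locus: RepeatLocus,
    ref_seq: str,
    sample_variants: list[tuple[VariantRecord, int]],
    seq_start: int = 1,
    flank_window: int = 50,
) -> tuple[RepeatCall, RepeatCall]:
    """Call the diplotype of one sample from its (variant, allele-count) list.

    Allele counts are diploid {1, 2}. Without phase information at most one
    heterozygous variant can be placed per haplotype; two or more overlapping
    in-scope variants with unknown phase yield an ``AMBIGUOUS`` diplotype.
    """
    in_scope: list[tuple[VariantRecord, int]] = []
    for var, count in sample_variants:
        if count not in (1, 2):
            continue
        v = normalize_variant(ref_seq, var, seq_start=seq_start)
        if (
            v.pos + len(v.ref) - 1 >= locus.tract.start - flank_window
            and v.pos <= locus.tract.end + flank_window
        ):
            in_scope.append((v, count))

    ref_call = RepeatCall(AlleleClass.REF, unit_count=locus.ref_units)
    if not in_scope:
        return (ref_call, ref_call)
    if len(in_scope) == 1:
        v, count = in_scope[0]
        call = call_repeat_allele(
            locus, ref_seq, v, seq_start=seq_start, flank_window=flank_window
        )
        if count == 2:
            return (call, call)
        return (ref_call, call)
    # multiple in-scope variants: placeable only if all homozygous (then each
    # haplotype carries all of them -- still ambiguous to apply jointly unless
    # they do not overlap; keep the conservative contract)
    amb = RepeatCall(AlleleClass.AMBIGUOUS)
    return (amb, amb)
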