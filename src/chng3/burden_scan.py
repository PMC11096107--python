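"""Windowed rare-variant density scan over a linkage region.

The locus-finding computation: a candidate region is partitioned into
fixed-width bins (500 bp by default), cohort variants are classified as
rare against a reference-panel allele-frequency table (AF < 0.002 by
default, strict), and each bin's case/control carrier counts are compared
with a one-sided Fisher exact test under Bonferroni family-wise control
(alpha / number-of-bins).

The 2x2 unit defaults to *individuals* (carrier vs non-carrier per group),
which keeps rows summing to group sizes when a person carries several rare
variants in one bin; an allele-count mode and a per-family collapse mode
are available as explicit switches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort_stats import TwoByTwo, fisher_exact_one_sided
from .formats_io import (
    CohortVariants,
    GenomicInterval,
    PanelFrequencies,
    ValidationError,
)
from .repeat_genotyper import normalize_variant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    region: GenomicInterval
    bin_width: int = 500
    rare_threshold: float = 0.002
    alpha: float = 0.05
    side: str = "cases"       # direction of the one-sided test
    unit: str = "carrier"     # "carrier" | "allele"
    family_of: dict[str, str] | None = None  # sample -> family; enables per-family collapse

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValidationError("bin_width must be >= 1")
        if not 0 < self.rare_threshold < 1:
            raise ValidationError("rare_threshold must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")
        if self.side != "cases":
            raise ValidationError("only enrichment-in-cases is supported")
        if self.unit not in ("carrier", "allele"):
            raise ValidationError(f"unknown counting unit {self.unit!r}")


@dataclass(frozen=True)
class BinResult:
    bin: GenomicInterval
    a: int  # case carriers (or alt alleles)
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers
    p: float
    neg_log10_p: float
    significant: bool


@dataclass
class ScanResult:
    bins: list[BinResult]
    threshold: float            # Bonferroni alpha / m
    ranking: list[int] = field(default_factory=list)  # bin indices, ascending p

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.bins)

    def top(self) -> BinResult:
        return self.bins[self.ranking[0]]


def make_bins(region: GenomicInterval, bin_width: int) -> list[GenomicInterval]:
    """Consecutive non-overlapping left-aligned bins whose union is the region.

    The last bin is truncated at ``region.end`` when the region length is not
    divisible by ``bin_width``; a width larger than the region yields a
    single truncated bin.
    """
    if bin_width < 1:
        raise ValidationError("bin_width must be >= 1")
    bins = []
    start = region.start
    while start <= region.end:
        bins.append(
            GenomicInterval(region.chrom, start, min(start + bin_width - 1, region.end))
        )
        start += bin_width
    return bins


def classify_rare(
    cohort: CohortVariants,
    panel: PanelFrequencies,
    rare_threshold: float = 0.002,
) -> set[tuple[str, int, str, str]]:
    """Variant keys with panel AF strictly below the threshold.

    Variants absent from the panel are treated as AF 0, hence rare.
    """
    return {
        v.key() for v in cohort.variants if panel.get(v.key()) < rare_threshold
    }


def count_bin_carriers(
    cohort: CohortVariants,
    rare_set: set[tuple[str, int, str, str]],
    bins: list[GenomicInterval],
    unit: str = "carrier",
    family_of: dict[str, str] | None = None,
) -> list[TwoByTwo]:
    """Per-bin 2x2 tables of rare-variant carriage in cases vs controls.

    A carrier is an individual with >= 1 non-missing alternate allele at
    >= 1 rare variant in the bin; missing genotypes never count as carriage
    and never shrink group denominators. Variants falling outside the
    binned region are ignored (logged). With ``family_of`` set, the counting
    unit becomes the family: a family carries if any member does.
    """
    if not bins:
        raise ValidationError("no bins")
    region_chrom = bins[0].chrom
    starts = np.array([b.start for b in bins])
    case_mask = np.array([cohort.group[s] == "case" for s in cohort.samples])

    bin_of: list[int | None] = []
    n_outside = 0
    for v in cohort.variants:
        if v.chrom != region_chrom or not (
            bins[0].start <= v.pos <= bins[-1].end
        ):
            bin_of.append(None)
            n_outside += 1
            continue
        bin_of.append(int(np.searchsorted(starts, v.pos, side="right")) - 1)
    if n_outside:
        logger.info("%d variants outside the scanned region ignored", n_outside)

    geno = cohort.genotypes
    tables: list[TwoByTwo] = []
    if unit == "allele":
        alt = np.where(geno > 0, geno, 0)  # missing -> 0 alt alleles
        n_case_alleles = 2 * int(case_mask.sum())
        n_ctrl_alleles = 2 * int((~case_mask).sum())
        for bi in range(len(bins)):
            idx = [i for i, b in enumerate(bin_of) if b == bi]
            a = int(alt[idx][:, case_mask].sum()) if idx else 0
            c = int(alt[idx][:, ~case_mask].sum()) if idx else 0
            tables.append(
                TwoByTwo(a, n_case_alleles - a, c, n_ctrl_alleles - c)
            )
        return tables

    carrier = geno > 0  # missing (-1) is False
    if family_of is not None:
        fam_ids = [family_of.get(s, s) for s in cohort.samples]
        case_fams = sorted({f for f, m in zip(fam_ids, case_mask) if m})
        ctrl_fams = sorted({f for f, m in zip(fam_ids, case_mask) if not m})
        fam_index = {f: i for i, f in enumerate(case_fams + ctrl_fams)}
        agg = np.zeros((len(geno), len(fam_index)), dtype=bool)
        for j, f in enumerate(fam_ids):
            agg[:, fam_index[f]] |= carrier[:, j]
        carrier = agg
        case_mask = np.array(
            [True] * len(case_fams) + [False] * len(ctrl_fams)
        )
    n_cases = int(case_mask.sum())
    n_controls = int((~case_mask).sum())
    for bi in range(len(bins)):
        idx = [i for i, b in enumerate(bin_of) if b == bi]
        if idx:
            any_carrier = carrier[idx].any(axis=0)
            a = int(any_carrier[case_mask].sum())
            c = int(any_carrier[~case_mask].sum())
        else:
            a = c = 0
        tables.append(TwoByTwo(a, n_cases - a, c, n_controls - c))
    return tables


def run_scan(
    cohort: CohortVariants,
    panel: PanelFrequencies,
    config: ScanConfig,
    ref_seq: str | None = None,
    seq_start: int = 1,
) -> ScanResult:
    """Full scan: bin, classify rarity, count, test, Bonferroni-rank.

    When ``ref_seq`` is supplied, variants are left-normalized against it
    before bin assignment (indel representations inside repeats otherwise
    shift bin boundaries).
    """
    if not cohort.cases or not cohort.controls:
        raise ValidationError("scan needs both cases and controls")
    if ref_seq is not None:
        cohort = CohortVariants(
            [normalize_variant(ref_seq, v, seq_start) for v in cohort.variants],
            cohort.samples,
            cohort.group,
            cohort.genotypes,
        )
    bins = make_bins(config.region, config.bin_width)
    m = len(bins)
    threshold = config.alpha / m
    rare = classify_rare(cohort, panel, config.rare_threshold)
    tables = count_bin_carriers(
        cohort, rare, bins, unit=config.unit, family_of=config.family_of
    )
    results: list[BinResult] = []
    for b, t in zip(bins, tables):
        fr = fisher_exact_one_sided(t)
        results.append(
            BinResult(
                bin=b,
                a=t.a, b=t.b, c=t.c, d=t.d,
                p=fr.p,
                neg_log10_p=-fr.log10_p,
                significant=fr.p < threshold,
            )
        )
    ranking = sorted(
        range(m), key=lambda i: (results[i].p, results[i].bin.start)
    )
    return ScanResult(bins=results, threshold=threshold, ranking=ranking)


def write_scan_tsv(result: ScanResult, path: str) -> None:
    """TSV: bin coordinates (1-based inclusive), 2x2 cells, p, -log10 p, flag."""
    with open(path, "w") as fh:
        fh.write("# one-sided Fisher exact test, Bonferroni threshold "
                 f"{result.threshold:.6g}\n")
        fh.write("chrom\tstart\tend\ta\tb\tc\td\tp\tneg_log10_p\tsignificant\n")
        for r in result.bins:
            fh.write(
                f"{r.bin.chrom}\t{r.bin.start}\t{r.bin.end}\t"
                f"{r.a}\t{r.b}\t{r.c}\t{r.d}\t"
                f"{r.p:.6g}\t{r.neg_log10_p:.4f}\t{int(r.significant)}\n"
            )
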