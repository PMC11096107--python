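"""Binning, rarity classification, carrier counting and the full window scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chng3.burden_scan import (
    ScanConfig,
    classify_rare,
    count_bin_carriers,
    make_bins,
    run_scan,
)
from chng3.formats_io import (
    CohortVariants,
    GenomicInterval,
    PanelFrequencies,
    ValidationError,
    VariantRecord,
)

SCAN_REGION = GenomicInterval("chr15", 86_206_001, 89_412_500)


class TestMakeBins:
    def test_scan_region_partitions_into_6413_full_bins(self):
        bins = make_bins(SCAN_REGION, 500)
        assert len(bins) == 6_413
        assert all(b.length() == 500 for b in bins)

    def test_exact_division(self):
        bins = make_bins(GenomicInterval("chr1", 1, 1000), 500)
        assert [b.length() for b in bins] == [500, 500]

    def test_truncated_last_bin(self):
        bins = make_bins(GenomicInterval("chr1", 1, 1001), 500)
        assert [b.length() for b in bins] == [500, 500, 1]

    def test_width_exceeding_region_gives_single_bin(self):
        bins = make_bins(GenomicInterval("chr1", 10, 20), 500)
        assert len(bins) == 1
        assert bins[0].length() == 11

    @settings(deadline=None, max_examples=50)
    @given(
        start=st.integers(1, 10**6),
        length=st.integers(1, 10**5),
        width=st.integers(1, 10**4),
    )
    def test_bins_disjoint_and_cover_region(self, start, length, width):
        region = GenomicInterval("chr1", start, start + length - 1)
        bins = make_bins(region, width)
        assert bins[0].start == region.start
        assert bins[-1].end == region.end
        for b1, b2 in zip(bins, bins[1:]):
            assert b2.start == b1.end + 1
        assert sum(b.length() for b in bins) == region.length()


def cohort_with(genos, groups, positions, refs=None, alts=None):
    n_var = len(positions)
    variants = [
        VariantRecord(
            "chr15", positions[i],
            (refs or ["A"] * n_var)[i], (alts or ["T"] * n_var)[i],
        )
        for i in range(n_var)
    ]
    samples = list(groups)
    return CohortVariants(variants, samples, groups, np.array(genos, dtype=np.int8))


class TestClassifyRare:
    def test_strict_threshold(self):
        cohort = cohort_with(
            [[1], [1], [1]],
            {"s1": "case"},
            [86_206_001, 86_206_002, 86_206_003],
        )
        panel = PanelFrequencies(
            {
                cohort.variants[0].key(): 0.0019,
                cohort.variants[1].key(): 0.002,
            }
        )
        rare = classify_rare(cohort, panel, 0.002)
        assert cohort.variants[0].key() in rare       # 0.0019 < 0.002
        assert cohort.variants[1].key() not in rare   # 0.002 is not rare
        assert cohort.variants[2].key() in rare       # absent from panel


class TestCountBinCarriers:
    def test_two_variants_one_bin_counted_once(self):
        groups = {"s1": "case", "s2": "control"}
        cohort = cohort_with(
            [[1, 0], [1, 0]], groups, [86_206_010, 86_206_020]
        )
        bins = make_bins(GenomicInterval("chr15", 86_206_001, 86_206_500), 500)
        tables = count_bin_carriers(cohort, {v.key() for v in cohort.variants}, bins)
        assert (tables[0].a, tables[0].b, tables[0].c, tables[0].d) == (1, 0, 0, 1)

    def test_empty_bin_table(self):
        groups = {f"c{i}": "case" for i in range(3)} | {f"k{i}": "control" for i in range(4)}
        cohort = cohort_with([[0] * 7], groups, [86_206_010])
        bins = make_bins(GenomicInterval("chr15", 86_206_001, 86_207_000), 500)
        t = count_bin_carriers(cohort, set(), bins)[1]
        assert (t.a, t.b, t.c, t.d) == (0, 3, 0, 4)

    def test_missing_genotypes_never_carry(self):
        groups = {"s1": "case", "s2": "case", "s3": "control"}
        cohort = cohort_with([[1, -1, 0]], groups, [86_206_010])
        bins = [GenomicInterval("chr15", 86_206_001, 86_206_500)]
        t = count_bin_carriers(cohort, {cohort.variants[0].key()}, bins)[0]
        # the missing individual is not a carrier but stays in the denominator
        assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 1)

    def test_shared_deletion_in_8_of_11_families(self):
        # 25 patients from 11 families vs 56 controls; the deletion is carried
        # by members of 8 families and no controls
        family_of = {}
        samples = {}
        idx = 0
        members_per_family = [3, 3, 3, 2, 2, 2, 2, 2, 2, 2, 2]  # 25 patients
        for fam, size in enumerate(members_per_family):
            for _ in range(size):
                sid = f"p{idx:02d}"
                samples[sid] = "case"
                family_of[sid] = f"FAM{fam}"
                idx += 1
        for i in range(56):
            sid = f"k{i:02d}"
            samples[sid] = "control"
            family_of[sid] = f"CTRL{i}"
        carrier_families = {f"FAM{i}" for i in range(8)}
        row = [
            1 if samples[s] == "case" and family_of[s] in carrier_families else 0
            for s in samples
        ]
        cohort = cohort_with(
            [row], samples, [88_569_433],
            refs=["GTTTG"], alts=["G"],
        )
        bins = make_bins(GenomicInterval("chr15", 88_569_001, 88_569_500), 500)
        t = count_bin_carriers(
            cohort, {cohort.variants[0].key()}, bins, family_of=family_of
        )[0]
        assert (t.a, t.b) == (8, 3)     # 8 of 11 case families carry
        assert (t.c, t.d) == (0, 56)


class TestRunScan:
    def test_threshold_is_alpha_over_m(self):
        groups = {"s1": "case", "s2": "control"}
        cohort = cohort_with([[1, 0]], groups, [86_206_010])
        res = run_scan(cohort, PanelFrequencies(), ScanConfig(region=SCAN_REGION))
        assert res.threshold == pytest.approx(0.05 / 6_413)

    def test_identical_groups_nothing_significant(self):
        groups = {"s1": "case", "s2": "control"}
        cohort = cohort_with(
            [[1, 1], [1, 1]], groups, [86_206_010, 86_207_010]
        )
        res = run_scan(
            cohort,
            PanelFrequencies(),
            ScanConfig(region=GenomicInterval("chr15", 86_206_001, 86_208_000)),
        )
        assert res.n_significant == 0

    def test_requires_both_groups(self):
        cohort = cohort_with([[1, 1]], {"s1": "case", "s2": "case"}, [86_206_010])
        with pytest.raises(ValidationError):
            run_scan(cohort, PanelFrequencies(), ScanConfig(region=SCAN_REGION))

    def test_ranking_ties_break_by_position(self):
        groups = {"s1": "case", "s2": "control"}
        cohort = cohort_with([[0, 0]], groups, [86_206_010])
        region = GenomicInterval("chr15", 86_206_001, 86_208_000)
        res = run_scan(cohort, PanelFrequencies(), ScanConfig(region=region))
        assert res.ranking == sorted(
            res.ranking, key=lambda i: (res.bins[i].p, res.bins[i].bin.start)
        )

    def test_p_invariant_under_relabeling_within_groups(self):
        rng = np.random.default_rng(5)
        groups = {f"s{i}": ("case" if i < 5 else "control") for i in range(12)}
        genos = rng.integers(0, 2, size=(6, 12))
        positions = [86_206_010 + 600 * i for i in range(6)]
        cohort = cohort_with(genos.tolist(), groups, positions)
        region = GenomicInterval("chr15", 86_206_001, 86_210_000)
        cfg = ScanConfig(region=region)
        panel = PanelFrequencies()
        base = [b.p for b in run_scan(cohort, panel, cfg).bins]
        # swap two cases and two controls (labels follow the samples)
        order = [1, 0, 2, 3, 4, 6, 5, 7, 8, 9, 10, 11]
        shuffled = CohortVariants(
            cohort.variants,
            [cohort.samples[i] for i in order],
            cohort.group,
            cohort.genotypes[:, order],
        )
        assert [b.p for b in run_scan(shuffled, panel, cfg).bins] == pytest.approx(base)

    def test_allele_count_mode_rows_sum_to_allele_numbers(self):
        groups = {"s1": "case", "s2": "case", "s3": "control"}
        cohort = cohort_with([[2, 1, 0]], groups, [86_206_010])
        res = run_scan(
            cohort,
            PanelFrequencies(),
            ScanConfig(
                region=GenomicInterval("chr15", 86_206_001, 86_206_500),
                unit="allele",
            ),
        )
        b = res.bins[0]
        assert (b.a, b.b) == (3, 1)   # 3 alt alleles of 4 case alleles
        assert (b.c, b.d) == (0, 2)
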