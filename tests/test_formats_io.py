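"""Format round trips, coordinate conventions and validation errors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chng3.formats_io import (
    CohortVariants,
    CoverageTrack,
    FormatError,
    GenomicInterval,
    PanelFrequencies,
    ValidationError,
    VariantRecord,
    read_bedgraph,
    read_panel_tsv,
    read_ped,
    read_vcf_lite,
    write_bedgraph,
    write_panel_tsv,
    write_ped,
    write_vcf_lite,
)


def small_cohort():
    variants = [
        VariantRecord("chr15", 100, "A", "T"),
        VariantRecord("chr15", 250, "GTTTG", "G"),
        VariantRecord("chr15", 300, "C", "G", id="rs1"),
    ]
    samples = ["s1", "s2", "s3"]
    group = {"s1": "case", "s2": "case", "s3": "control"}
    geno = np.array([[0, 1, 2], [1, 0, -1], [2, 2, 0]], dtype=np.int8)
    return CohortVariants(variants, samples, group, geno)


class TestGenomicInterval:
    def test_length_is_inclusive(self):
        assert GenomicInterval("chr15", 86_206_051, 89_412_131).length() == 3_206_081

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 0, 5)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 9)

    @given(st.integers(1, 10**6), st.integers(0, 10**4))
    def test_length_matches_base_count(self, start, extra):
        iv = GenomicInterval("chr1", start, start + extra)
        assert iv.length() == extra + 1
        # 1-based inclusive s..e covers the same bases as 0-based (s-1, e)
        assert iv.length() == iv.end - (iv.start - 1)

    def test_parse_tolerates_commas(self):
        iv = GenomicInterval.parse("chr15:86,206,001-89,412,500")
        assert (iv.start, iv.end) == (86_206_001, 89_412_500)


class TestVcfLite:
    def test_round_trip_identity(self, tmp_path):
        cohort = small_cohort()
        path = tmp_path / "c.vcf"
        write_vcf_lite(cohort, str(path))
        assert read_vcf_lite(str(path)) == cohort

    def test_round_trip_readable_by_pysam(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        cohort = small_cohort()
        path = tmp_path / "c.vcf"
        write_vcf_lite(cohort, str(path))
        with pysam.VariantFile(str(path)) as vf:
            recs = list(vf)
        assert [r.pos for r in recs] == [v.pos for v in cohort.variants]
        assert list(recs[0].samples) == cohort.samples
        # GT 1/1 for s3 at the first record
        assert recs[0].samples["s3"]["GT"] == (1, 1)

    def test_multiallelic_row_splits_sharing_pos_ref(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##SAMPLE=<ID=s1,Group=case>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t10\t.\tG\tA,T\t.\t.\t.\tGT\t1/2\n"
        )
        c = read_vcf_lite(str(path))
        assert [v.key() for v in c.variants] == [
            ("chr1", 10, "G", "A"),
            ("chr1", 10, "G", "T"),
        ]
        # the 1/2 genotype carries one copy of each alternate
        assert c.genotypes[:, 0].tolist() == [1, 1]

    def test_gt_codes(self, tmp_path):
        path = tmp_path / "g.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "chr1\t10\t.\tG\tA\t.\t.\t.\tGT\t1/1\t0|1\t./.\n"
        )
        c = read_vcf_lite(str(path), groups={"s1": "case", "s2": "case", "s3": "control"})
        assert c.genotypes[0].tolist() == [2, 1, -1]

    def test_malformed_gt_names_line(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t10\t.\tG\tA\t.\t.\t.\tGT\t0/1\n"
            "chr1\t11\t.\tG\tA\t.\t.\t.\tGT\tfoo\n"
        )
        with pytest.raises(FormatError, match="line 4"):
            read_vcf_lite(str(path), groups={"s1": "case"})

    def test_duplicate_sample_rejected(self, tmp_path):
        path = tmp_path / "dup.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts1\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            read_vcf_lite(str(path), groups={"s1": "case"})

    def test_missing_group_label_rejected(self, tmp_path):
        path = tmp_path / "ng.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
        )
        with pytest.raises(ValidationError, match="label"):
            read_vcf_lite(str(path))


class TestPed:
    def test_trio_round_trip(self, tmp_path):
        path = tmp_path / "t.ped"
        path.write_text(
            "F1 1 0 0 1 2 1 2\n"
            "F1 2 0 0 2 1 3 3\n"
            "F1 3 1 2 1 0 1 3\n"
        )
        peds = read_ped(str(path))
        ped = peds["F1"]
        assert len(ped.nonfounders()) == 1
        assert ped.individuals["3"].affection == "unknown"
        assert ped.individuals["1"].marker_genotypes == [(1, 2)]
        out = tmp_path / "o.ped"
        write_ped(peds, str(out))
        assert read_ped(str(out))["F1"].individuals.keys() == ped.individuals.keys()

    def test_absent_parent_is_link_error(self, tmp_path):
        path = tmp_path / "bad.ped"
        path.write_text("F1 3 9 2 1 2\nF1 2 0 0 2 1\n")
        with pytest.raises(ValidationError, match="parent 9 absent"):
            read_ped(str(path))

    def test_own_ancestor_is_cycle_error(self, tmp_path):
        path = tmp_path / "cyc.ped"
        path.write_text("F1 1 2 3 1 2\nF1 2 1 3 1 1\nF1 3 0 0 2 1\n")
        with pytest.raises(ValidationError, match="cycle"):
            read_ped(str(path))


class TestBedgraph:
    def test_single_record_fills_one_bin(self, tmp_path):
        p = tmp_path / "a.bedgraph"
        p.write_text("chr15\t0\t100\t5.0\n")
        track = read_bedgraph(str(p), bin_width=100)
        assert track.depths.tolist() == [5.0]

    def test_record_spanning_two_bins_gives_both_the_value(self, tmp_path):
        p = tmp_path / "b.bedgraph"
        p.write_text("chr15\t50\t150\t7.0\n")
        track = read_bedgraph(
            str(p), bin_width=100, interval=GenomicInterval("chr15", 1, 200)
        )
        assert track.depths.tolist() == [7.0, 7.0]

    def test_empty_file_gives_zero_track(self, tmp_path):
        p = tmp_path / "e.bedgraph"
        p.write_text("")
        track = read_bedgraph(
            str(p), bin_width=100, interval=GenomicInterval("chr15", 1, 300)
        )
        assert track.depths.tolist() == [0.0, 0.0, 0.0]

    def test_overlapping_intervals_rejected(self, tmp_path):
        p = tmp_path / "o.bedgraph"
        p.write_text("chr15\t0\t100\t1.0\nchr15\t50\t150\t2.0\n")
        with pytest.raises(ValidationError, match="overlap"):
            read_bedgraph(str(p), bin_width=100)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "n.bedgraph"
        p.write_text("chr15\t0\t100\t-1.0\n")
        with pytest.raises(ValidationError, match="negative"):
            read_bedgraph(str(p), bin_width=100)

    def test_round_trip_of_bin_aligned_track(self, tmp_path):
        iv = GenomicInterval("chr15", 1, 500)
        track = CoverageTrack("CT001", iv, 100, [1.0, 0.0, 2.5, 3.0, 0.5])
        p = tmp_path / "t.bedgraph"
        write_bedgraph(track, str(p))
        back = read_bedgraph(str(p), bin_width=100, interval=iv, cell_type="CT001")
        assert np.allclose(back.depths, track.depths)


def test_panel_tsv_round_trip(tmp_path):
    panel = PanelFrequencies(
        {("chr15", 100, "A", "T"): 0.0015, ("chr15", 200, "G", "GT"): 0.25}
    )
    p = tmp_path / "panel.tsv"
    write_panel_tsv(panel, str(p))
    back = read_panel_tsv(str(p))
    assert back.af == pytest.approx(panel.af)
    assert back.get(("chrX", 1, "A", "T")) == 0.0  # absent -> AF 0


@settings(deadline=None, max_examples=25)
@given(
    n_var=st.integers(0, 8),
    n_samp=st.integers(1, 6),
    seed=st.integers(0, 10**6),
)
def test_vcf_round_trip_on_random_cohorts(tmp_path_factory, n_var, n_samp, seed):
    rng = np.random.default_rng(seed)
    variants = [
        VariantRecord("chr15", int(p), "A", "T")
        for p in sorted(rng.choice(10**6, size=n_var, replace=False) + 1)
    ]
    samples = [f"s{i}" for i in range(n_samp)]
    group = {s: ("case" if i % 2 else "control") for i, s in enumerate(samples)}
    geno = rng.integers(-1, 3, size=(n_var, n_samp)).astype(np.int8)
    cohort = CohortVariants(variants, samples, group, geno)
    path = tmp_path_factory.mktemp("rt") / "c.vcf"
    write_vcf_lite(cohort, str(path))
    assert read_vcf_lite(str(path)) == cohort
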