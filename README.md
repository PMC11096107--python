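# chng3

A tested, reusable implementation of the computational discovery chain used
to map a dominant familial thyroid disorder (nongoitrous congenital
hypothyroidism with adult multinodular goiter) to a noncoding **(TTTG)₄
microsatellite** on chromosome 15q26.1 — exercisable entirely on seeded
synthetic data, with no external downloads.

It is aimed at statistical geneticists and methodologists who want each
stage of such a mapping study as a small, verifiable component:

1. **Parametric linkage** (`chng3.linkage_lod`) — two-point pedigree
   likelihoods by Elston–Stewart peeling under a fully penetrant autosomal
   dominant model (disease allele frequency 10⁻⁴, no phenocopies,
   affected-only), with LOD(θ) = log₁₀ L(θ) − log₁₀ L(0.5) and a
   brute-force enumeration oracle.
2. **Rare-variant window scan** (`chng3.burden_scan`) — a 3.2-Mb candidate
   region split into 500-bp bins (the chr15:86,206,001–89,412,500 region
   gives exactly m = 6,413), variants classified rare when the reference
   panel allele frequency is < 0.002, per-bin case/control carrier 2×2
   tables tested with a one-sided Fisher exact test against the Bonferroni
   threshold α/m = 0.05/6,413 ≈ 7.8 × 10⁻⁶.
3. **Microsatellite genotyping** (`chng3.repeat_genotyper`) — parsimonious
   left-aligned indel normalization, maximal perfect-repeat-run location,
   and allele classification: (TTTG)₃ unit loss, (TTTG)₅ unit gain,
   repeat-internal SNV, or other.
4. **Haplotype segregation** (`chng3.pedigree_haplotypes`) — Mendelian
   consistency, de novo detection with parentage support, rule-based
   transmission phasing of the variant-bearing chromosome, and a
   conservative "at least k founder haplotypes" count.
5. **Chromatin-accessibility selectivity** (`chng3.atac_selectivity`) —
   selectivity(target) = median₁₀₀bp-bin depth of the target cell type /
   Σ over all cell types of median depths, over 154 cell-type tracks.
6. **Cohort statistics** (`chng3.cohort_stats`) — log-space hypergeometric
   Fisher tail (no underflow), Wilson/Clopper–Pearson proportion intervals,
   "1 in N" prevalence, Welch's t.
7. **Synthetic data** (`chng3.synthetic_data`) — seeded generators for every
   input with truth records, so each stage's statistical behaviour (type-I
   rate, power, parameter recovery) is testable.

## Worked example

Run the whole chain on synthetic data (simulate → scan → repeat genotyping →
haplotype phasing → statistics → selectivity):

```sh
chng3 demo --seed 7 --out-dir demo_out
```

```
INFO chng3: demo complete: top bin chr15:86316501-86317000 (truth match: True),
k founders 4, target selectivity 0.0374
```

The manifest (`demo_out/manifest.json`) records every seed and parameter.
With seed 7 the scan of a 500-bin region (25 cases vs 56 controls, one
spiked window at 70% case carriage) reports the spiked bin —
`chr15:86316501-86317000`, p = 1.05 × 10⁻¹², the only bin under the
Bonferroni threshold 10⁻⁴ — and it matches the generator's truth record.
The repeat caller classifies the emulated pathogenic 4-bp deletion as
`UNIT_LOSS` with unit count 3 (four TTTG copies reduced to three); the
founder-haplotype count recovers k = 4 from 12 synthetic families; and the
target cell type's selectivity at the spiked peak is 0.0374 against a
baseline expectation of 1/154 ≈ 0.0065.

Individual stages are also exposed:

```sh
chng3 stats fisher --table 3,30,3,38719
# p = 1.122921e-08 (log10 p = -7.9497)
chng3 stats prevalence --carriers 3 --panel 38722
# 1/12,900 (95% CI 1/4,390 to 1/38,000, wilson)
chng3 scan --vcf cohort.vcf --panel panel.tsv \
      --region chr15:86206001-89412500 --bin-width 500 \
      --rare-af 0.002 --alpha 0.05 --out scan.tsv
```

The first command reproduces the enrichment of 3 carriers among 33
multinodular-goiter patients against 3 carriers among 38,722 reference-panel
individuals; the second inverts the panel carrier proportion into a
population prevalence.

## Layout

```
src/chng3/          library (one module per pipeline stage)
tests/              pytest suite, including end-to-end acceptance checks
scripts/acceptance.py
docs/methods.md     models, assumptions, numerical choices, limitations
```
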