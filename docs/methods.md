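# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices a maintainer should know about.

## Coordinates and formats

All internal coordinates are 1-based inclusive (`GenomicInterval`), the
convention in which clinical variant positions are printed; conversion to
0-based half-open happens only at the bedGraph/BED boundary (a 1-based
interval `s..e` covers the bases of the 0-based pair `(s-1, e)`). VCF input
is a GT-only v4.2 subset parsed in-package so that malformed rows can be
reported with line numbers; multi-allelic rows are split into biallelic
records before any counting, because rarity classification and repeat
calling are per-allele. Missing genotypes (`./.`) never count as carriage
and never shrink group denominators. Case/control labels ride in
`##SAMPLE=<ID=...,Group=...>` header lines (an explicit `groups=` mapping
overrides), which keeps write∘read an identity.

## Rare-variant window scan

The candidate region is partitioned into consecutive left-aligned bins of
`bin_width` (default 500 bp; the chr15:86,206,001–89,412,500 region is
exactly divisible, giving m = 6,413 full bins — the final bin is truncated
when a region is not divisible). A variant is *rare* iff its reference-panel
allele frequency is strictly below `rare_threshold` (default 0.002);
variants absent from the panel count as frequency 0. Each bin yields a 2×2
table — by default *individuals* (carrier = ≥1 non-missing alternate allele
at ≥1 rare variant in the bin) per group, which keeps rows summing to group
sizes when one person carries several variants. Because the original table
construction behind such scans is typically under-specified, an
allele-count mode (`unit="allele"`) and a per-family collapse mode
(`family_of=`, counting each family once) are provided as explicit
switches; related individuals are otherwise counted independently and no
kinship adjustment is applied. The test is the one-sided Fisher exact test
(enrichment in cases) with Bonferroni control at α/m; ranking is by
ascending p with genomic-position tie-breaks. Indels are left-normalized
against the reference before bin assignment when a sequence is supplied, so
equivalent representations cannot straddle a bin boundary.

## Two-point parametric linkage

The disease model is a diallelic locus with penetrance vector
(f₀, f₁, f₂) = (0, 1, 1) — fully penetrant dominant, no phenocopies — and
disease allele frequency 10⁻⁴. `affected_only=True` (default) replaces
"unaffected" phenotypes with "unknown" (penetrance factor 1), the standard
guard against late-onset misclassification. The pedigree likelihood at
recombination fraction θ sums over ordered two-locus haplotype pairs per
individual: founder priors are Hardy–Weinberg with linkage-equilibrium
haplotype frequencies (disease frequency × marker allele frequency — the
standard LINKAGE convention); a parent with ordered haplotypes (h₁, h₂)
transmits h₁ or h₂ unrecombined with probability (1−θ)/2 each and the two
recombinant haplotypes with probability θ/2 each; observed marker genotypes
enter as unordered-pair indicators. θ is sex-averaged.

The sum is computed by Elston–Stewart peeling, realized as exact variable
elimination on the pedigree's factor graph: the child factor
P(g_c | g_f, g_m) factorizes into a paternal and a maternal half, so all
factors are at most pairwise; variables are eliminated greedily by smallest
merged clique, and each intermediate table is rescaled by its maximum with
the log accumulated, so likelihoods far below float underflow remain exact
in log space. Looped (consanguineous) pedigrees are rejected rather than
broken — correctness over coverage at this scale. Mendelian-impossible
marker data returns −∞ rather than raising.

Only the two-point statistic is implemented: multipoint computation was
delegated to an external engine in the study this emulates, and the
two-point likelihood preserves the model while remaining verifiable against
the shipped brute-force oracle (`brute_force_log_likelihood`, an
independently coded scalar enumeration limited to ≤10 members). LOD(θ) =
log₁₀ L(θ) − log₁₀ L(0.5); LOD(0.5) = 0 by construction, and the default θ
grid is 0, 0.01, …, 0.5.

A useful analytic fixture: a pedigree with n phase-known, fully informative,
non-recombinant affected meioses has LOD(0) = n·log₁₀ 2 — but only in the
q → 0 limit of the disease allele frequency; at q = 10⁻⁴ carrier-spouse
configurations contribute O(q·2ⁿ) (≈0.047 LOD at n = 10). Tests of the
closed form therefore use q = 10⁻⁸.

## Microsatellite genotyping

Indels inside a repeat tract admit many equivalent VCF representations, so
every variant is normalized first: shared suffixes then prefixes are
trimmed to the minimal form (≥1 base on each side for indels), then indels
are shifted left while the preceding base matches — one canonical
left-aligned key per variant, accepting either left- or right-shifted
input. The repeat tract is located as the maximal run of *perfect* unit
copies overlapping an anchor, scanning all phases; an SNV inside the tract
therefore shortens the perfect run, and it is the classifier, not the
count, that carries the SNV semantics. Classification applies the variant
to the reference and re-locates the tract: a pure length change by a
multiple of the unit confined to the tract is `UNIT_LOSS`/`UNIT_GAIN` with
the new count; a single-base in-tract substitution without length change is
`SNV_DISRUPTED`; variants more than 50 bp (configurable) from the tract are
`OUT_OF_SCOPE`; anything else is `OTHER`. Diplotypes place one heterozygous
in-scope variant per haplotype; two or more unphased in-scope variants
yield `AMBIGUOUS` rather than a guess. Processing is plus-strand only.

The packaged reference around the (TTTG)₄ tract is synthetic: random flanks
with the tract placed at the printed chromosome coordinates
(chr15:88,569,434–88,569,449), boundary bases constrained to {A, C} so no
stray unit abuts the tract and left-alignment stays anchored. The true
genomic flanking sequence is deliberately not embedded; coordinates are
preserved for realism, sequence content is not.

## Haplotype segregation and founder counting

Mendelian checks flag a child whose unordered genotype cannot be formed
from one allele of each *genotyped* parent (missing data never violates).
De novo status requires a carrier child, both parents genotyped
non-carriers, and a violation-free child — violations demote the call to
"parentage-questioned", an ungenotyped parent to "indeterminate". Phasing
is rule-based transmission phasing: at each marker, the allele
co-transmitted with carrier status across informative carrier-parent →
carrier-child meioses is assigned to the carrier haplotype; a homozygous
carrier phases a marker trivially; contradictory assignments (recombination
or genotyping error) set the marker to missing with a logged conflict — no
probabilistic reconstruction and no recombination model inside the small
marker window. Founder counting groups haplotypes that match exactly on
every jointly non-missing marker (union-find over the compatibility
relation), after dropping haplotypes below `min_completeness` (default
0.5). Missing data can only merge groups, so k is a lower bound — "at
least k independent origins" — and k is monotone non-increasing as markers
are removed. No stepwise-mutation tolerance is applied.

## Chromatin-accessibility selectivity

Coverage is carried as mean read depth in fixed bins (default 100 bp)
anchored at each track's declared interval start — matching precomputed-bin
workflows — and a query region's summary is the median over the bins it
overlaps, partial bins included whole. The selectivity of a target cell
type over a region is its median depth divided by the sum of all cell
types' median depths; scores sum to 1 whenever the total is positive, are
invariant to common rescaling, and an all-zero region is flagged undefined
rather than raising. The even-count median is the midpoint of the two
central values. The number of cell types (154 in the emulated atlas) is a
parameter, not a constant.

## Exact statistics

The one-sided Fisher test is the upper hypergeometric tail P(X ≥ a) given
the table margins, accumulated in log space via log-gamma and log-sum-exp,
so p-values down to log₁₀ p ≈ −10⁶ stay representable; an exact rational
mode (`exact=True`) is available for small tables and agrees with the
log-space path to 12 significant digits. Proportion intervals default to
Wilson with Clopper–Pearson available; the output labels its method because
published screening intervals often leave the method unreported and neither
standard interval need reproduce a printed one exactly. Prevalence is
reported as "1 in N" with N rounded to 3 significant figures and the chosen
interval inverted. Welch's t uses the Welch–Satterthwaite degrees of
freedom, with degenerate zero-variance cases handled explicitly (equal
means → p = 1; differing means → p = 0 with a warning).

## Synthetic-data generators

All generators are pure functions of (config, seed) — one
`numpy.random.default_rng` stream per call; derived sub-seeds stay below
2³¹ — and every generator returns a truth record sufficient to score its
downstream stage.

* **Cohort**: 25 cases vs 56 controls by default (the sequenced discovery
  cohort's sizes), private heterozygous background SNVs at 0.01 per kb per
  individual — giving each person on the order of 30 rare variants over a
  3.2-Mb region, the density scale of the emulated data — plus optional
  common-variant distractors at panel frequency ≥ the rarity cutoff, and
  one spiked shared 4-bp deletion carried by 70%/0% of cases/controls by
  default. Panel frequencies keep every generated rare variant strictly
  below the cutoff. Not emulated: linkage disequilibrium, mutation-rate
  heterogeneity, sequencing error, relatedness — so passing tests speak to
  the counting and testing machinery, not to robustness against cryptic
  structure in real cohorts.
* **Pedigrees**: gene dropping over a template (default: an 8-member
  three-generation family) with one linked marker; the first founder is
  seeded as a heterozygous carrier by default, because a disease family is
  ascertained, not sampled — at a 10⁻⁴ allele frequency an unconditioned
  drop almost never segregates. The default marker has four equifrequent
  alleles: two-point linkage in practice uses informative multi-allelic
  STRs, and a biallelic marker leaves half of meioses uninformative (the
  200-pedigree recovery experiment then cannot resolve loose linkage).
* **Founder haplotypes**: each family is a nuclear pedigree whose
  variant-bearing chromosome copies one of k distinct founder haplotypes
  over a 5-STR + 4-SNP panel (every founder used at least once); two
  carrier children per family make phasing ambiguity at any marker require
  two independent coincidences. No recombination or STR mutation within
  the window.
* **Coverage tracks**: shared Gaussian baseline noise (truncated at 0) with
  an additive peak on the target cell type only.
* **Repeat reference**: see above. A small fixed reporter-assay fixture
  (hexaplicate control mean 1.0 vs treated mean 0.68, ~6% spread) is
  shipped for Welch-test demonstrations; its values are inputs, not
  measurements.

## Experiment sizes

The verification experiments run at sizes chosen to give stable Monte-Carlo
estimates on a single CPU: 100 random small pedigrees for the
peeling-vs-enumeration oracle, 200 pedigrees per θ for recovery at
θ ∈ {0, 0.1, 0.3} (±0.05 acceptance), 200 null simulations of a 500-bin
region for the family-wise type-I rate and 100 seeds for spiked-bin
recovery, and 50 seeds for phasing-truth comparison.

## Known limitations

Two-point linkage only; no loop breaking; no covariate or kinship
adjustment in the scan; exact-match founder grouping (no STR stepwise
tolerance); plus-strand repeat calling from normalized variants rather than
reads; bedGraph text rather than bigWig binary input; the printed
confidence intervals of published screening studies are method-dependent
and are not asserted against any specific interval here.
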