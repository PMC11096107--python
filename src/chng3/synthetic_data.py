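"""Seeded generators emulating every input the pipeline consumes.

Each generator is a pure function of its config and seed (one
``numpy.random.default_rng`` stream per call), and each returns a *truth
record* sufficient to score the downstream stage it feeds: the spiked bin
index for the burden scan, the true recombination fraction and founder
haplotypes for linkage, the founder-haplotype assignment for segregation
analysis, and the peak location for the selectivity score.

Default study conditions mirror the discovery cohort being emulated:
25 sequenced patients vs 56 sequenced controls, rare variants at panel
allele frequency < 0.002, 500-bp scan bins, a fully penetrant autosomal
dominant disease model with disease-allele frequency 1e-4, five STR + four
SNP segregation markers, and 154 cell-type coverage tracks binned at
100 bp. The background rare-variant rate defaults to 0.01 per kb per
individual, giving each person on the order of 30 rare variants across a
3.2-Mb region — the density scale seen in the emulated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .burden_scan import make_bins
from .formats_io import (
    CohortVariants,
    CoverageTrack,
    GenomicInterval,
    Individual,
    PanelFrequencies,
    Pedigree,
    ValidationError,
    VariantRecord,
)
from .pedigree_haplotypes import Marker, MarkerPanel
from .repeat_genotyper import RepeatLocus

_BASES = "ACGT"


class ConfigError(ValidationError):
    pass


# ---------------------------------------------------------------------------
# Case/control cohort with one spiked window
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    region: GenomicInterval
    n_cases: int = 25
    n_controls: int = 56
    bin_width: int = 500
    background_rare_rate: float = 0.01   # expected rare variants / person / kb
    spiked_bin_index: int | None = None
    spike_carrier_fraction_cases: float = 0.7
    spike_carrier_fraction_controls: float = 0.0
    panel_absent_prob: float = 0.5       # chance a rare variant is absent from panel
    n_common_variants: int = 20          # common (AF >= threshold) distractors
    rare_threshold: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.spike_carrier_fraction_cases,
            self.spike_carrier_fraction_controls,
            self.panel_absent_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.background_rare_rate < 0:
            raise ConfigError("negative background rate")
        if self.region.length() < self.bin_width:
            raise ConfigError("region shorter than one bin")
        n_bins = -(-self.region.length() // self.bin_width)
        if self.spiked_bin_index is not None and not (
            0 <= self.spiked_bin_index < n_bins
        ):
            raise ConfigError(
                f"spiked bin {self.spiked_bin_index} outside 0..{n_bins - 1}"
            )


def _ref_base(pos: int) -> str:
    # deterministic per-position reference base so colliding draws agree
    return _BASES[pos % 4]


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[CohortVariants, PanelFrequencies, dict]:
    """Case/control cohort with private background rare variants and,
    optionally, one spiked 500-bp window shared across carriers.

    Background variants are private SNVs (one heterozygous carrier each)
    placed uniformly; the spiked variant is a shared 4-bp deletion inside
    the chosen bin, carried heterozygously by the configured fraction of
    each group. Panel AFs keep every generated "rare" variant strictly
    below ``rare_threshold``; common distractor variants sit at or above it.
    """
    rng = np.random.default_rng(config.seed)
    region = config.region
    samples = [f"case{i:03d}" for i in range(config.n_cases)] + [
        f"ctrl{i:03d}" for i in range(config.n_controls)
    ]
    group = {
        s: ("case" if s.startswith("case") else "control") for s in samples
    }
    n_samples = len(samples)

    bins = make_bins(region, config.bin_width)
    records: dict[tuple[str, int, str, str], np.ndarray] = {}
    panel: dict[tuple[str, int, str, str], float] = {}
    rare_keys: list[tuple[str, int, str, str]] = []

    def add_genotype(key: tuple[str, int, str, str], sample_idx: int, count: int) -> None:
        row = records.setdefault(key, np.zeros(n_samples, dtype=np.int8))
        row[sample_idx] = count

    # background: private heterozygous SNVs
    lam = config.background_rare_rate * region.length() / 1000.0
    for j in range(n_samples):
        for pos in rng.integers(
            region.start, region.end + 1, size=rng.poisson(lam)
        ):
            pos = int(pos)
            ref = _ref_base(pos)
            alt = _BASES[(pos + 1 + int(rng.integers(0, 3))) % 4]
            if alt == ref:
                alt = _BASES[(_BASES.index(ref) + 1) % 4]
            key = (region.chrom, pos, ref, alt)
            add_genotype(key, j, 1)
            if key not in panel:
                absent = rng.random() < config.panel_absent_prob
                panel_af = (
                    0.0
                    if absent
                    else float(rng.uniform(1e-5, config.rare_threshold * 0.999))
                )
                if not absent:
                    panel[key] = panel_af
                rare_keys.append(key)

    # common distractors: everyone may carry, AF >= threshold
    for _ in range(config.n_common_variants):
        pos = int(rng.integers(region.start, region.end + 1))
        ref = _ref_base(pos)
        alt = _BASES[(_BASES.index(ref) + 2) % 4]
        key = (region.chrom, pos, ref, alt)
        af = float(rng.uniform(config.rare_threshold, 0.5))
        panel[key] = af
        carriers = rng.random(n_samples) < af
        row = records.setdefault(key, np.zeros(n_samples, dtype=np.int8))
        row[carriers] = 1

    spike_carriers: list[str] = []
    if config.spiked_bin_index is not None:
        b = bins[config.spiked_bin_index]
        pos = min(b.start + 10, b.end - 5)
        ref = _ref_base(pos) + "TTTG"
        key = (region.chrom, pos, ref, ref[0])
        for j, s in enumerate(samples):
            frac = (
                config.spike_carrier_fraction_cases
                if group[s] == "case"
                else config.spike_carrier_fraction_controls
            )
            if rng.random() < frac:
                add_genotype(key, j, 1)
                spike_carriers.append(s)
        if spike_carriers:
            panel[key] = 3 / 38722  # ultrarare in the emulated panel
            rare_keys.append(key)

    keys = sorted(records)
    variants = [VariantRecord(k[0], k[1], k[2], k[3]) for k in keys]
    genotypes = (
        np.stack([records[k] for k in keys])
        if keys
        else np.zeros((0, n_samples), dtype=np.int8)
    )
    cohort = CohortVariants(variants, samples, group, genotypes)
    truth = {
        "spiked_bin_index": config.spiked_bin_index,
        "spiked_bin": (
            str(bins[config.spiked_bin_index])
            if config.spiked_bin_index is not None
            else None
        ),
        "spike_carriers": spike_carriers,
        "n_bins": len(bins),
        "seed": config.seed,
    }
    return cohort, PanelFrequencies(panel, n_panel=38722), truth


# ---------------------------------------------------------------------------
# Dominant pedigrees with a linked marker
# ---------------------------------------------------------------------------

# template rows: (iid, father, mother, sex)
TEMPLATE_TRIO = (("1", None, None, 1), ("2", None, None, 2), ("3", "1", "2", 1))

TEMPLATE_NUCLEAR_4 = TEMPLATE_TRIO + (("4", "1", "2", 2),)

TEMPLATE_THREE_GEN = (
    ("gf", None, None, 1),
    ("gm", None, None, 2),
    ("fa", "gf", "gm", 1),
    ("mo", None, None, 2),
    ("c1", "fa", "mo", 1),
    ("c2", "fa", "mo", 2),
    ("c3", "fa", "mo", 1),
    ("c4", "fa", "mo", 2),
)


@dataclass(frozen=True)
class PedigreeSimConfig:
    template: tuple = TEMPLATE_THREE_GEN
    disease_allele_freq: float = 0.0001
    penetrance: tuple[float, float, float] = (0.0, 1.0, 1.0)
    theta_true: float = 0.0
    # four equifrequent alleles: an informative STR-like linkage marker
    marker_allele_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    force_carrier_founder: bool = True
    family_id: str = "F1"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 <= p <= 1 for p in self.penetrance):
            raise ConfigError("penetrances must be in [0, 1]")
        if not 0.0 <= self.theta_true <= 0.5:
            raise ConfigError("theta_true must be in [0, 0.5]")


def simulate_pedigree(config: PedigreeSimConfig) -> tuple[Pedigree, dict]:
    """Gene-drop a disease locus and one linked marker through a template.

    Founders draw haplotypes from population frequencies; with
    ``force_carrier_founder`` (the default — a disease family is
    ascertained, not sampled at random) the first founder is made a
    heterozygous carrier. Transmission is Mendelian with recombination
    ``theta_true``; affection is assigned by penetrance on the disease
    genotype.
    """
    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.marker_allele_freqs)
    if freqs.min() <= 0 or not np.isclose(freqs.sum(), 1.0):
        raise ConfigError("marker allele frequencies must be positive, sum 1")

    ids = [row[0] for row in config.template]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate template ids")

    def draw_marker() -> int:
        return int(rng.choice(len(freqs), p=freqs)) + 1

    def founder_hap(carrier: bool) -> tuple[int, int]:
        d = 1 if carrier else (1 if rng.random() < config.disease_allele_freq else 0)
        return (d, draw_marker())

    haps: dict[str, tuple[tuple[int, int], tuple[int, int]]] = {}
    individuals: dict[str, Individual] = {}
    first_founder = next(r[0] for r in config.template if r[1] is None)
    for iid, father, mother, sex in config.template:
        if father is None:
            force = config.force_carrier_founder and iid == first_founder
            haps[iid] = (founder_hap(force), founder_hap(False))
        else:
            if father not in haps or mother not in haps:
                raise ConfigError(f"template row {iid}: parents must precede children")
            gametes = []
            for parent in (father, mother):
                c = int(rng.integers(0, 2))
                d = haps[parent][c][0]
                if rng.random() < config.theta_true:
                    c = 1 - c
                gametes.append((d, haps[parent][c][1]))
            haps[iid] = (gametes[0], gametes[1])
        ndis = haps[iid][0][0] + haps[iid][1][0]
        affected = rng.random() < config.penetrance[ndis]
        individuals[iid] = Individual(
            family=config.family_id,
            iid=iid,
            father=father,
            mother=mother,
            sex=sex,
            affection="affected" if affected else "unaffected",
            marker_genotypes=[(haps[iid][0][1], haps[iid][1][1])],
        )
    ped = Pedigree(individuals)
    truth = {
        "theta_true": config.theta_true,
        "haplotypes": {iid: haps[iid] for iid in ids},
        "carrier": {iid: haps[iid][0][0] + haps[iid][1][0] > 0 for iid in ids},
        "seed": config.seed,
    }
    return ped, truth


# ---------------------------------------------------------------------------
# Founder haplotypes across families
# ---------------------------------------------------------------------------

DEFAULT_SEGREGATION_PANEL = MarkerPanel(
    tuple(
        [
            Marker(f"STR{i + 1}", "STR", 1000 * (i + 1), (0.125,) * 8)
            for i in range(5)
        ]
        + [
            Marker(f"SNP{i + 1}", "SNP", 10000 + 1000 * i, (0.5, 0.5))
            for i in range(4)
        ]
    )
)


def simulate_founder_haplotypes(
    k_founders: int,
    n_families: int,
    markers: MarkerPanel = DEFAULT_SEGREGATION_PANEL,
    seed: int = 0,
    n_carrier_children: int = 2,
) -> tuple[list[Pedigree], dict[str, dict[str, bool]], dict]:
    """Families whose variant-bearing chromosomes copy one of k founder haplotypes.

    Each family is a nuclear pedigree: a carrier father whose
    variant-bearing chromosome is one of ``k_founders`` distinct marker
    haplotypes, a non-carrier mother drawn from population frequencies, and
    ``n_carrier_children`` carrier children who inherit the founder
    haplotype intact (no recombination across the small marker window).
    Every founder haplotype is used at least once. Returns (pedigrees,
    carrier status per family, truth).
    """
    if k_founders < 1:
        raise ConfigError("k_founders must be >= 1")
    if k_founders > n_families:
        raise ConfigError("k_founders cannot exceed n_families")
    rng = np.random.default_rng(seed)

    def draw_hap() -> tuple[int, ...]:
        return tuple(
            int(rng.choice(len(m.allele_freqs), p=m.allele_freqs)) + 1
            for m in markers.markers
        )

    founder_haps: list[tuple[int, ...]] = []
    while len(founder_haps) < k_founders:
        h = draw_hap()
        if h not in founder_haps:
            founder_haps.append(h)

    assignment = list(range(k_founders)) + [
        int(rng.integers(0, k_founders)) for _ in range(n_families - k_founders)
    ]

    pedigrees: list[Pedigree] = []
    carrier_status: dict[str, dict[str, bool]] = {}
    for fi, founder_idx in enumerate(assignment):
        fam = f"FAM{fi + 1:03d}"
        fhap = founder_haps[founder_idx]
        father_other = draw_hap()
        mother_haps = (draw_hap(), draw_hap())
        inds: dict[str, Individual] = {
            "fa": Individual(fam, "fa", None, None, 1, "affected",
                             [tuple(sorted((a, b))) for a, b in zip(fhap, father_other)]),
            "mo": Individual(fam, "mo", None, None, 2, "unaffected",
                             [tuple(sorted(p)) for p in zip(*mother_haps)]),
        }
        status = {"fa": True, "mo": False}
        for ci in range(n_carrier_children):
            mat = mother_haps[int(rng.integers(0, 2))]
            inds[f"c{ci + 1}"] = Individual(
                fam, f"c{ci + 1}", "fa", "mo", int(rng.integers(1, 3)), "affected",
                [tuple(sorted((a, b))) for a, b in zip(fhap, mat)],
            )
            status[f"c{ci + 1}"] = True
        pedigrees.append(Pedigree(inds))
        carrier_status[fam] = status

    truth = {
        "k_founders": k_founders,
        "founder_haplotypes": founder_haps,
        "assignment": {f"FAM{fi + 1:03d}": a for fi, a in enumerate(assignment)},
        "seed": seed,
    }
    return pedigrees, carrier_status, truth


# ---------------------------------------------------------------------------
# Cell-type coverage tracks
# ---------------------------------------------------------------------------

def default_cell_type_names(n: int, target: str | None = None) -> list[str]:
    names = [f"CT{i + 1:03d}" for i in range(n)]
    if target and target not in names:
        names[0] = target
    return names


def simulate_coverage_tracks(
    interval: GenomicInterval,
    peak_region: GenomicInterval,
    target_cell_type: str = "thyroid_follicular",
    n_cell_types: int = 154,
    peak_height: float = 5.0,
    baseline: float = 1.0,
    noise_sd: float = 0.1,
    bin_width: int = 100,
    cell_type_names: list[str] | None = None,
    seed: int = 0,
) -> tuple[list[CoverageTrack], dict]:
    """Coverage tracks sharing baseline noise, one with an added peak.

    The target cell type gains ``peak_height`` over every bin overlapping
    ``peak_region``; all tracks share the same noise law (truncated at 0).
    """
    names = cell_type_names or default_cell_type_names(n_cell_types, target_cell_type)
    if len(names) != n_cell_types:
        raise ConfigError("cell_type_names length != n_cell_types")
    if target_cell_type not in names:
        raise ConfigError(f"unknown target cell type {target_cell_type!r}")
    if not (
        peak_region.chrom == interval.chrom
        and peak_region.start >= interval.start
        and peak_region.end <= interval.end
    ):
        raise ConfigError("peak region outside declared interval")
    rng = np.random.default_rng(seed)
    n_bins = -(-interval.length() // bin_width)
    first = (peak_region.start - interval.start) // bin_width
    last = (peak_region.end - interval.start) // bin_width
    tracks = []
    for name in names:
        depths = np.clip(baseline + rng.normal(0, noise_sd, n_bins), 0, None)
        if name == target_cell_type:
            depths[first: last + 1] += peak_height
        tracks.append(CoverageTrack(name, interval, bin_width, depths))
    truth = {
        "target_cell_type": target_cell_type,
        "peak_region": str(peak_region),
        "peak_bins": (int(first), int(last)),
        "peak_height": peak_height,
        "seed": seed,
    }
    return tracks, truth


# ---------------------------------------------------------------------------
# Repeat-locus reference sequence
# ---------------------------------------------------------------------------

def make_repeat_locus_reference(
    flank_length: int = 200,
    n_units: int = 4,
    seed: int = 0,
    unit: str = "TTTG",
    tract_start: int = 88_569_434,
    chrom: str = "chr15",
) -> tuple[str, RepeatLocus, int]:
    """Synthetic reference around a perfect repeat tract at printed coordinates.

    Random flanks are constrained so no extra copy of the unit abuts the
    tract (boundary bases are drawn from {A, C}), keeping the tract maximal
    and indel left-alignment anchored at the tract. Returns
    ``(sequence, locus, seq_start)`` where ``seq_start`` is the chromosome
    coordinate of the first sequence base.
    """
    if flank_length < 20:
        raise ConfigError("flank_length must be >= 20")
    if n_units < 1:
        raise ConfigError("n_units must be >= 1")
    rng = np.random.default_rng(seed)

    def flank(n: int) -> str:
        return "".join(_BASES[i] for i in rng.integers(0, 4, n))

    left = flank(flank_length - 1) + "AC"[int(rng.integers(0, 2))]
    right = "AC"[int(rng.integers(0, 2))] + flank(flank_length - 1)
    # scrub any stray unit copy adjacent to the tract boundary
    while left[-len(unit):] == unit:
        left = left[: -len(unit)] + flank(len(unit) - 1) + "A"
    while right[: len(unit)] == unit:
        right = "A" + flank(len(unit) - 1) + right[len(unit):]
    seq = left + unit * n_units + right
    tract = GenomicInterval(chrom, tract_start, tract_start + n_units * len(unit) - 1)
    locus = RepeatLocus(chrom=chrom, tract=tract, unit=unit, ref_units=n_units)
    seq_start = tract_start - flank_length
    return seq, locus, seq_start


# ---------------------------------------------------------------------------
# Reporter-assay fixture
# ---------------------------------------------------------------------------

# Normalized luciferase activity, hexaplicate: promoter-only control vs the
# repressor construct (mean 0.68 of control, i.e. a 32% reduction with ~6%
# spread). Fixture inputs for welch_t_test demos, not measured data.
LUCIFERASE_CONTROL = (0.94, 1.03, 0.98, 1.06, 0.97, 1.02)
LUCIFERASE_TREATED = (0.61, 0.72, 0.66, 0.74, 0.63, 0.72)
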