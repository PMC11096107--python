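"""Readers and writers for the formats every pipeline stage touches.

Coordinate conventions
----------------------
Internally everything is 1-based inclusive (:class:`GenomicInterval`),
matching how genomic positions are printed in the clinical-genetics
literature. Conversion to 0-based half-open happens only at format
boundaries (bedGraph/BED input). A 1-based interval ``s..e`` covers the
same bases as the 0-based half-open pair ``(s-1, e)``.

Supported formats: a GT-only subset of VCF v4.2, LINKAGE pre-makeped PED,
bedGraph, FASTA (via Biopython), and TSV panel-frequency tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1  # genotype allele-count sentinel

_DNA = re.compile(r"^[ACGT]+$")


class FormatError(ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class ValidationError(ValueError):
    """Structurally parseable input that violates a semantic invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValidationError(f"end {self.end} < start {self.start}")

    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` (commas in numbers tolerated)."""
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text.strip())
        if not m:
            raise ValidationError(f"cannot parse interval {text!r}")
        return cls(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant; ``pos`` is the 1-based position of the first REF base."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt must be nonempty")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not _DNA.match(allele):
                raise ValidationError(f"allele {allele!r} not over ACGT")

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class CohortVariants:
    """Per-sample allele counts over normalized biallelic variant records.

    ``genotypes`` is an int matrix of shape (n_variants, n_samples) with
    entries in {0, 1, 2} or :data:`MISSING`.
    """

    variants: list[VariantRecord]
    samples: list[str]
    group: dict[str, str]  # sample -> "case" | "control"
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} != "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        for s in self.samples:
            if self.group.get(s) not in ("case", "control"):
                raise ValidationError(f"sample {s!r} lacks a case/control label")

    @property
    def cases(self) -> list[str]:
        return [s for s in self.samples if self.group[s] == "case"]

    @property
    def controls(self) -> list[str]:
        return [s for s in self.samples if self.group[s] == "control"]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortVariants):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and self.group == other.group
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class PanelFrequencies:
    """Reference-panel allele frequencies keyed by normalized variant key."""

    af: dict[tuple[str, int, str, str], float] = field(default_factory=dict)
    n_panel: int | None = None  # number of individuals behind the panel

    def __post_init__(self) -> None:
        for k, f in self.af.items():
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"frequency {f} for {k} outside [0, 1]")

    def get(self, key: tuple[str, int, str, str]) -> float:
        """AF for a variant key; absent variants are treated as AF 0."""
        return self.af.get(key, 0.0)


AFFECTION = {0: "unknown", 1: "unaffected", 2: "affected"}


@dataclass
class Individual:
    family: str
    iid: str
    father: str | None
    mother: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    affection: str  # "affected" | "unaffected" | "unknown"
    marker_genotypes: list[tuple[int, int]] = field(default_factory=list)
    # (0, 0) = missing at that marker

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """One family: individuals with resolved parent links and marker genotypes."""

    individuals: dict[str, Individual]

    def __post_init__(self) -> None:
        for ind in self.individuals.values():
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self.individuals:
                    raise ValidationError(
                        f"individual {ind.iid}: parent {parent} absent from family"
                    )
            if (ind.father is None) != (ind.mother is None):
                raise ValidationError(
                    f"individual {ind.iid}: exactly one parent specified"
                )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValidationError(f"pedigree cycle through {iid}: {stack}")
            state[iid] = 0
            ind = self.individuals[iid]
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    visit(parent, stack + [iid])
            state[iid] = 1

        for iid in self.individuals:
            visit(iid, [])

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.is_founder]

    def nonfounders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if not i.is_founder]

    def children_of(self, iid: str) -> list[Individual]:
        return [
            i for i in self.individuals.values() if iid in (i.father, i.mother)
        ]

    def topological_order(self) -> list[Individual]:
        """Founders first, every parent before its children."""
        order: list[Individual] = []
        done: set[str] = set()

        def visit(iid: str) -> None:
            if iid in done:
                return
            ind = self.individuals[iid]
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    visit(parent)
            done.add(iid)
            order.append(ind)

        for iid in self.individuals:
            visit(iid)
        return order

    @property
    def family_id(self) -> str:
        return next(iter(self.individuals.values())).family

    def __len__(self) -> int:
        return len(self.individuals)


@dataclass
class CoverageTrack:
    """Mean read depth of one cell type over fixed-width bins of an interval.

    ``depths[i]`` covers 1-based positions
    ``interval.start + i*bin_width .. interval.start + (i+1)*bin_width - 1``
    (last bin truncated at ``interval.end``).
    """

    cell_type: str
    interval: GenomicInterval
    bin_width: int
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.bin_width < 1:
            raise ValidationError("bin_width must be >= 1")
        if np.any(self.depths < 0):
            raise ValidationError("negative depth")
        n_expected = -(-self.interval.length() // self.bin_width)
        if len(self.depths) != n_expected:
            raise ValidationError(
                f"{len(self.depths)} bins but interval needs {n_expected}"
            )

    def n_bins(self) -> int:
        return len(self.depths)


# ---------------------------------------------------------------------------
# VCF-lite (GT-only subset of VCF v4.2)
# ---------------------------------------------------------------------------

_GT_RE = re.compile(r"^(\.|\d+)([/|])(\.|\d+)$")

_VCF_COLUMNS = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]


def read_vcf_lite(path: str, groups: Mapping[str, str] | None = None) -> CohortVariants:
    """Read a GT-only VCF v4.2 subset into a :class:`CohortVariants`.

    Multi-allelic rows are split into biallelic records sharing POS/REF.
    Diploid GT fields are parsed to alternate-allele counts; ``./.`` becomes
    missing. Case/control labels come from ``groups`` or, failing that, from
    ``##SAMPLE=<ID=...,Group=...>`` header lines.
    """
    header_groups: dict[str, str] = {}
    samples: list[str] = []
    variants: list[VariantRecord] = []
    rows: list[list[int]] = []
    saw_columns = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                m = re.match(r"##SAMPLE=<ID=([^,>]+),Group=([^,>]+)>", line)
                if m:
                    header_groups[m.group(1)] = m.group(2)
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if cols[: len(_VCF_COLUMNS)] != _VCF_COLUMNS:
                    raise FormatError(
                        f"malformed column header: {cols[:9]}", line=lineno
                    )
                samples = cols[len(_VCF_COLUMNS):]
                if len(set(samples)) != len(samples):
                    raise ValidationError(f"duplicate sample id in header (line {lineno})")
                saw_columns = True
                continue
            if not saw_columns:
                raise FormatError("data before #CHROM header", line=lineno)
            fields = line.split("\t")
            if len(fields) != len(_VCF_COLUMNS) + len(samples):
                raise FormatError(
                    f"expected {len(_VCF_COLUMNS) + len(samples)} columns, got {len(fields)}",
                    line=lineno,
                )
            chrom, pos_s, vid, ref, alt_s, _qual, _filt, _info, fmt = fields[:9]
            if fmt.split(":")[0] != "GT":
                raise FormatError(f"FORMAT must lead with GT, got {fmt!r}", line=lineno)
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"non-integer POS {pos_s!r}", line=lineno) from None
            alts = alt_s.split(",")
            counts_per_alt = [[0] * len(samples) for _ in alts]
            for j, cell in enumerate(fields[9:]):
                gt = cell.split(":")[0]
                m = _GT_RE.match(gt)
                if not m:
                    raise FormatError(f"malformed GT {gt!r} for sample {samples[j]}", line=lineno)
                alleles = [m.group(1), m.group(3)]
                if "." in alleles:
                    for c in counts_per_alt:
                        c[j] = MISSING
                    continue
                for a in map(int, alleles):
                    if a > len(alts):
                        raise FormatError(
                            f"GT allele index {a} exceeds ALT count {len(alts)}",
                            line=lineno,
                        )
                    if a > 0:
                        counts_per_alt[a - 1][j] += 1
            for k, alt in enumerate(alts):
                variants.append(
                    VariantRecord(
                        chrom, pos, ref, alt, id=None if vid == "." else vid
                    )
                )
                rows.append(counts_per_alt[k])

    if not saw_columns:
        raise FormatError("missing #CHROM header line")
    group = dict(groups) if groups is not None else header_groups
    missing_labels = [s for s in samples if s not in group]
    if missing_labels:
        raise ValidationError(f"no case/control label for samples {missing_labels}")
    genotypes = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return CohortVariants(variants, samples, {s: group[s] for s in samples}, genotypes)


def write_vcf_lite(cohort: CohortVariants, path: str) -> None:
    """Write one biallelic row per record; group labels go in SAMPLE headers."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=chng3\n")
        for s in cohort.samples:
            fh.write(f"##SAMPLE=<ID={s},Group={cohort.group[s]}>\n")
        fh.write("\t".join(_VCF_COLUMNS + cohort.samples) + "\n")
        for i, v in enumerate(cohort.variants):
            cells = [gt_map[int(g)] for g in cohort.genotypes[i]]
            fh.write(
                "\t".join(
                    [v.chrom, str(v.pos), v.id or ".", v.ref, v.alt, ".", ".", ".", "GT"]
                    + cells
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# LINKAGE pre-makeped PED
# ---------------------------------------------------------------------------

def read_ped(path: str) -> dict[str, Pedigree]:
    """Read a whitespace-delimited LINKAGE PED file into one Pedigree per family.

    Columns: family, individual, father, mother, sex (1/2/0), phenotype
    (2=affected, 1=unaffected, 0=unknown), then marker allele pairs
    (0 = missing allele).
    """
    families: dict[str, dict[str, Individual]] = {}
    n_markers: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) < 6:
                raise FormatError(f"expected >= 6 columns, got {len(toks)}", line=lineno)
            fam, iid, father, mother, sex_s, pheno_s = toks[:6]
            marker_toks = toks[6:]
            if len(marker_toks) % 2:
                raise FormatError("odd number of marker allele columns", line=lineno)
            if n_markers is None:
                n_markers = len(marker_toks) // 2
            elif len(marker_toks) // 2 != n_markers:
                raise FormatError(
                    f"marker count {len(marker_toks) // 2} != first row's {n_markers}",
                    line=lineno,
                )
            try:
                sex = int(sex_s)
                pheno = int(pheno_s)
                alleles = [int(t) for t in marker_toks]
            except ValueError:
                raise FormatError("non-integer sex/phenotype/allele code", line=lineno) from None
            if sex not in (0, 1, 2):
                raise FormatError(f"sex code {sex} not in {{0,1,2}}", line=lineno)
            if pheno not in (0, 1, 2):
                raise FormatError(f"phenotype code {pheno} not in {{0,1,2}}", line=lineno)
            genos = [
                (alleles[2 * i], alleles[2 * i + 1]) for i in range(len(alleles) // 2)
            ]
            fam_dict = families.setdefault(fam, {})
            if iid in fam_dict:
                raise FormatError(f"duplicate individual {iid} in family {fam}", line=lineno)
            fam_dict[iid] = Individual(
                family=fam,
                iid=iid,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
                sex=sex,
                affection=AFFECTION[pheno],
                marker_genotypes=genos,
            )
    return {fam: Pedigree(inds) for fam, inds in families.items()}


def write_ped(pedigrees: Mapping[str, Pedigree] | Iterable[Pedigree], path: str) -> None:
    peds = (
        pedigrees.values() if isinstance(pedigrees, Mapping) else list(pedigrees)
    )
    code = {"unknown": 0, "unaffected": 1, "affected": 2}
    with open(path, "w") as fh:
        for ped in peds:
            for ind in ped.topological_order():
                row = [
                    ind.family,
                    ind.iid,
                    ind.father or "0",
                    ind.mother or "0",
                    str(ind.sex),
                    str(code[ind.affection]),
                ]
                for a, b in ind.marker_genotypes:
                    row += [str(a), str(b)]
                fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(
    path: str,
    bin_width: int,
    interval: GenomicInterval | None = None,
    cell_type: str | None = None,
) -> CoverageTrack:
    """Resample a bedGraph file onto fixed-width bins of ``interval``.

    Input intervals are 0-based half-open; they must not overlap each other
    and must carry non-negative values. Bin values are the coverage-weighted
    mean over the bases actually covered by records; bins touched by no
    record are 0. When ``interval`` is omitted it spans base 1 to the last
    covered base of the (single) chromosome in the file.
    """
    records: list[tuple[str, int, int, float]] = []  # chrom, start0, end0, value
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            toks = line.split()
            if len(toks) < 4:
                raise FormatError(f"expected 4 columns, got {len(toks)}", line=lineno)
            chrom = toks[0]
            try:
                s0, e0, val = int(toks[1]), int(toks[2]), float(toks[3])
            except ValueError:
                raise FormatError("non-numeric start/end/value", line=lineno) from None
            if e0 <= s0:
                raise FormatError(f"empty or inverted interval {s0}-{e0}", line=lineno)
            if val < 0:
                raise ValidationError(f"negative value {val} at line {lineno}")
            records.append((chrom, s0, e0, val))

    chroms = {r[0] for r in records}
    if interval is None:
        if not records:
            raise ValidationError("empty bedGraph and no interval given")
        if len(chroms) > 1:
            raise ValidationError(f"multiple chromosomes {sorted(chroms)}; pass interval")
        chrom = next(iter(chroms))
        interval = GenomicInterval(chrom, 1, max(r[2] for r in records))
    records = [r for r in records if r[0] == interval.chrom]

    records.sort(key=lambda r: r[1])
    for (_, s1, e1, _), (_, s2, _e2, _) in zip(records, records[1:]):
        if s2 < e1:
            raise ValidationError(
                f"overlapping bedGraph intervals {s1}-{e1} and starting {s2}"
            )

    n_bins = -(-interval.length() // bin_width)
    weighted = np.zeros(n_bins)
    covered = np.zeros(n_bins)
    # clip to the declared interval; convert to 0-based offsets within it
    lo0, hi0 = interval.start - 1, interval.end
    for _, s0, e0, val in records:
        s = max(s0, lo0)
        e = min(e0, hi0)
        if e <= s:
            continue
        first = (s - lo0) // bin_width
        last = (e - 1 - lo0) // bin_width
        for b in range(first, last + 1):
            b_lo = lo0 + b * bin_width
            b_hi = min(b_lo + bin_width, hi0)
            ov = min(e, b_hi) - max(s, b_lo)
            weighted[b] += val * ov
            covered[b] += ov
    depths = np.divide(weighted, covered, out=np.zeros(n_bins), where=covered > 0)
    return CoverageTrack(
        cell_type=cell_type or interval.chrom,
        interval=interval,
        bin_width=bin_width,
        depths=depths,
    )


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """One record per bin, 0-based half-open, skipping zero-depth bins."""
    with open(path, "w") as fh:
        lo0 = track.interval.start - 1
        for i, d in enumerate(track.depths):
            if d == 0:
                continue
            s0 = lo0 + i * track.bin_width
            e0 = min(s0 + track.bin_width, track.interval.end)
            fh.write(f"{track.interval.chrom}\t{s0}\t{e0}\t{d:g}\n")


# ---------------------------------------------------------------------------
# FASTA and panel tables
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str, descriptions: Mapping[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description=(descriptions or {}).get(name, ""))
        for name, s in seqs.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_panel_tsv(path: str) -> PanelFrequencies:
    """TSV with columns chrom, pos, ref, alt, af (header optional)."""
    af: dict[tuple[str, int, str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("chrom"):
                continue
            toks = line.split("\t")
            if len(toks) < 5:
                raise FormatError(f"expected 5 columns, got {len(toks)}", line=lineno)
            try:
                key = (toks[0], int(toks[1]), toks[2], toks[3])
                af[key] = float(toks[4])
            except ValueError:
                raise FormatError("bad pos/af value", line=lineno) from None
    return PanelFrequencies(af)


def write_panel_tsv(panel: PanelFrequencies, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\taf\n")
        for (chrom, pos, ref, alt), f in sorted(panel.af.items()):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{f:.6g}\n")
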