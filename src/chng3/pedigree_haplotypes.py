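"""Marker-based segregation analysis around a focal variant.

Given families genotyped for a small panel of STR/SNP markers flanking a
focal variant, this module answers the questions a segregation study asks:
are the genotypes Mendelian-consistent (supporting stated parentage), did
any child acquire the variant de novo, which marker alleles ride on the
variant-bearing chromosome (rule-based transmission phasing), and how many
distinct founder haplotypes carry the variant across families — the
"at least k independent origins" statistic.

Haplotype distinctness is judged by exact match on jointly non-missing
marker alleles; missing data can only merge groups, so the count is a
conservative lower bound, matching the "at least k chromosomes
independently" reading. No recombination or STR mutation model is applied
within the (small) marker window; phase conflicts across meioses are
logged and the marker set to missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .formats_io import Pedigree, ValidationError

logger = logging.getLogger(__name__)

MISSING_ALLELE = 0


@dataclass(frozen=True)
class Marker:
    name: str
    kind: str  # "STR" | "SNP"
    position: int
    allele_freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("STR", "SNP"):
            raise ValidationError(f"marker kind {self.kind!r}")


@dataclass(frozen=True)
class MarkerPanel:
    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValidationError("empty marker panel")
        pos = [m.position for m in self.markers]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValidationError("marker positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class CarrierHaplotype:
    """Ordered marker alleles on the variant-bearing chromosome of one family.

    ``alleles[i]`` is 0 (:data:`MISSING_ALLELE`) where phasing was
    uninformative or conflicting.
    """

    family: str
    alleles: tuple[int, ...]

    @property
    def completeness(self) -> float:
        return sum(a != MISSING_ALLELE for a in self.alleles) / len(self.alleles)


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def check_mendelian(ped: Pedigree) -> list[tuple[str, int]]:
    """(individual, marker index) pairs where a child's genotype cannot be
    formed from one allele of each genotyped parent.

    A missing parental genotype (any 0 allele) is never a violation at that
    marker, nor is a missing child genotype.
    """
    violations: list[tuple[str, int]] = []
    for ind in ped.nonfounders():
        father = ped.individuals[ind.father]
        mother = ped.individuals[ind.mother]
        for mi, child_g in enumerate(ind.marker_genotypes):
            if MISSING_ALLELE in child_g:
                continue
            fg = father.marker_genotypes[mi]
            mg = mother.marker_genotypes[mi]
            if MISSING_ALLELE in fg or MISSING_ALLELE in mg:
                continue
            c1, c2 = child_g
            ok = any(
                (c1 == pa and c2 == ma) or (c2 == pa and c1 == ma)
                for pa in fg
                for ma in mg
            )
            if not ok:
                violations.append((ind.iid, mi))
    return violations


# ---------------------------------------------------------------------------
# De novo detection
# ---------------------------------------------------------------------------

def detect_de_novo(
    ped: Pedigree, carrier_status: Mapping[str, bool | None]
) -> dict[str, str]:
    """Classify each non-founder's focal-variant origin.

    Statuses: ``"de_novo"`` (carrier child, both parents genotyped
    non-carriers, zero Mendelian violations in the family supporting true
    parentage), ``"transmitted"`` (a carrier parent exists),
    ``"parentage_questioned"`` (would be de novo but marker violations
    exist), ``"indeterminate"`` (a parent ungenotyped for the variant),
    ``"non_carrier"``.
    """
    violations = check_mendelian(ped)
    flagged = {iid for iid, _ in violations}
    out: dict[str, str] = {}
    for ind in ped.nonfounders():
        child_carrier = carrier_status.get(ind.iid)
        if not child_carrier:
            out[ind.iid] = "non_carrier"
            continue
        pf = carrier_status.get(ind.father)
        pm = carrier_status.get(ind.mother)
        if pf is None or pm is None:
            out[ind.iid] = "indeterminate"
        elif pf or pm:
            out[ind.iid] = "transmitted"
        elif ind.iid in flagged:
            out[ind.iid] = "parentage_questioned"
        else:
            out[ind.iid] = "de_novo"
    return out


# ---------------------------------------------------------------------------
# Transmission phasing
# ---------------------------------------------------------------------------

def _transmitted_allele(
    parent_g: tuple[int, int],
    other_g: tuple[int, int],
    child_g: tuple[int, int],
) -> int:
    """Allele the focal parent transmitted to the child, or 0 if ambiguous."""
    if MISSING_ALLELE in parent_g or MISSING_ALLELE in child_g:
        return MISSING_ALLELE
    if parent_g[0] == parent_g[1]:
        # homozygous parent transmits its only allele (if compatible)
        return parent_g[0] if parent_g[0] in child_g else MISSING_ALLELE
    candidates = set()
    for pa in set(parent_g):
        if pa not in child_g:
            continue
        # the other child allele must be attributable to the other parent
        rest = list(child_g)
        rest.remove(pa)
        other_allele = rest[0]
        if MISSING_ALLELE in other_g or other_allele in other_g:
            candidates.add(pa)
    return candidates.pop() if len(candidates) == 1 else MISSING_ALLELE


def phase_carriers(
    ped: Pedigree, carrier_status: Mapping[str, bool | None]
) -> CarrierHaplotype:
    """Reconstruct the carrier haplotype of one family by transmission phasing.

    At each marker, the allele co-transmitted with carrier status across
    informative carrier-parent -> carrier-child meioses is assigned to the
    carrier haplotype. A carrier whose genotype is homozygous at a marker
    phases that marker trivially. Contradictory assignments across meioses
    (recombination or genotyping error) set the marker to missing, logged.
    """
    n_markers = len(next(iter(ped.individuals.values())).marker_genotypes)
    assigned: list[int] = [MISSING_ALLELE] * n_markers
    conflict: list[bool] = [False] * n_markers

    def propose(mi: int, allele: int) -> None:
        if allele == MISSING_ALLELE or conflict[mi]:
            return
        if assigned[mi] == MISSING_ALLELE:
            assigned[mi] = allele
        elif assigned[mi] != allele:
            logger.warning(
                "family %s marker %d: conflicting phased alleles %d vs %d",
                ped.family_id, mi, assigned[mi], allele,
            )
            conflict[mi] = True
            assigned[mi] = MISSING_ALLELE

    meioses = 0
    for ind in ped.nonfounders():
        if not carrier_status.get(ind.iid):
            continue
        father = ped.individuals[ind.father]
        mother = ped.individuals[ind.mother]
        for parent, other in ((father, mother), (mother, father)):
            if carrier_status.get(parent.iid):
                meioses += 1
                for mi in range(n_markers):
                    propose(
                        mi,
                        _transmitted_allele(
                            parent.marker_genotypes[mi],
                            other.marker_genotypes[mi],
                            ind.marker_genotypes[mi],
                        ),
                    )

    if meioses == 0:
        # single genotyped carrier: only homozygous markers phase
        carriers = [
            ped.individuals[iid]
            for iid, st in carrier_status.items()
            if st and iid in ped.individuals
        ]
        if not carriers:
            raise ValidationError(
                f"family {ped.family_id}: no genotyped carrier to phase"
            )
        for c in carriers:
            for mi, (a1, a2) in enumerate(c.marker_genotypes):
                if a1 == a2 and a1 != MISSING_ALLELE:
                    propose(mi, a1)
    return CarrierHaplotype(family=ped.family_id, alleles=tuple(assigned))


# ---------------------------------------------------------------------------
# Founder-haplotype counting
# ---------------------------------------------------------------------------

@dataclass
class FounderGrouping:
    k: int
    groups: list[list[str]]  # families per group
    excluded: list[str] = field(default_factory=list)  # below completeness


def count_founder_haplotypes(
    haplotypes: Sequence[CarrierHaplotype],
    min_completeness: float = 0.5,
) -> FounderGrouping:
    """Number of distinct carrier haplotypes, conservatively.

    Haplotypes with completeness below ``min_completeness`` are excluded.
    Two haplotypes are merged when they match exactly on every marker where
    both are non-missing (union-find over the compatibility relation), so
    the returned ``k`` is an "at least k independent origins" lower bound.
    Empty input gives ``k = 0``.
    """
    kept = [h for h in haplotypes if h.completeness >= min_completeness]
    excluded = [h.family for h in haplotypes if h.completeness < min_completeness]
    n = len(kept)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def compatible(h1: CarrierHaplotype, h2: CarrierHaplotype) -> bool:
        return all(
            a == b
            for a, b in zip(h1.alleles, h2.alleles)
            if a != MISSING_ALLELE and b != MISSING_ALLELE
        )

    for i in range(n):
        for j in range(i + 1, n):
            if compatible(kept[i], kept[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[str]] = {}
    for i, h in enumerate(kept):
        groups.setdefault(find(i), []).append(h.family)
    return FounderGrouping(
        k=len(groups), groups=sorted(groups.values()), excluded=excluded
    )
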