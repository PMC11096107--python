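"""Two-point parametric linkage analysis for disease pedigrees.

Computes the pedigree likelihood of a diallelic disease locus against one
codominant marker at recombination fraction theta, under a user-specified
penetrance model — by default the fully penetrant autosomal dominant,
no-phenocopy, disease-allele-frequency 1e-4 model used for dominant
congenital disease mapping, in affected-only mode (unaffected relatives'
phenotypes treated as unknown, robust to late onset).

The likelihood is an Elston–Stewart peeling: founders carry
Hardy–Weinberg priors over ordered two-locus haplotype pairs (linkage
equilibrium between disease and marker), transmissions recombine with
probability theta, and phenotype/marker observations enter as penetrance
and indicator factors. Peeling is realized as exact variable elimination
over the pedigree's factor graph with per-step rescaling, so likelihoods
far below float underflow remain representable. The LOD score is
``log10 L(theta) - log10 L(0.5)``.

Multipoint analysis is deliberately out of scope: it preserves nothing of
the model that the two-point statistic does not, and two-point results are
verifiable against the brute-force enumeration oracle shipped alongside
(:func:`brute_force_log_likelihood`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .formats_io import Pedigree, ValidationError

LOG10 = math.log(10.0)


class PedigreeStructureError(ValueError):
    """Looped (consanguineous / multiply-married-into) pedigree."""


class SizeError(ValueError):
    """Pedigree too large for exhaustive enumeration."""


@dataclass(frozen=True)
class LinkageModel:
    """Single-locus disease model for parametric linkage.

    ``penetrance[i]`` is P(affected | i disease alleles); the phenocopy rate
    is ``penetrance[0]``. ``affected_only=True`` replaces every "unaffected"
    phenotype with "unknown" before computing the likelihood.
    """

    disease_allele_freq: float = 0.0001
    penetrance: tuple[float, float, float] = (0.0, 1.0, 1.0)
    affected_only: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.disease_allele_freq < 1:
            raise ValidationError("disease allele frequency must be in (0, 1)")
        if any(not 0 <= p <= 1 for p in self.penetrance):
            raise ValidationError("penetrances must be in [0, 1]")


@dataclass
class MarkerData:
    """One codominant marker: population allele frequencies + genotypes.

    Alleles are numbered 1..n; ``genotypes[iid]`` is an unordered pair or
    ``None`` for untyped individuals.
    """

    allele_freqs: Sequence[float]
    genotypes: Mapping[str, tuple[int, int] | None]

    def __post_init__(self) -> None:
        f = np.asarray(self.allele_freqs, dtype=float)
        if np.any(f <= 0) or not math.isclose(f.sum(), 1.0, rel_tol=1e-9):
            raise ValidationError("marker allele frequencies must be positive and sum to 1")

    @property
    def n_alleles(self) -> int:
        return len(self.allele_freqs)

    @classmethod
    def from_pedigree(
        cls, ped: Pedigree, allele_freqs: Sequence[float], marker_index: int = 0
    ) -> "MarkerData":
        genos: dict[str, tuple[int, int] | None] = {}
        for iid, ind in ped.individuals.items():
            g = ind.marker_genotypes[marker_index]
            genos[iid] = None if 0 in g else g
        return cls(allele_freqs, genos)


@dataclass
class LodCurve:
    thetas: np.ndarray
    lod: np.ndarray
    theta_max: float
    lod_max: float


# ---------------------------------------------------------------------------
# Shared model pieces
# ---------------------------------------------------------------------------
# Haplotype index h = d * a + (m - 1): d in {0, 1} (1 = disease allele),
# marker allele m in 1..a. Ordered genotype g = h_pat * (2a) + h_mat.

def _check_no_loops(ped: Pedigree) -> None:
    g = nx.Graph()
    for ind in ped.individuals.values():
        g.add_node(("i", ind.iid))
        if not ind.is_founder:
            mate = ("m", (ind.father, ind.mother))
            g.add_edge(("i", ind.father), mate)
            g.add_edge(("i", ind.mother), mate)
            g.add_edge(mate, ("i", ind.iid))
    if nx.cycle_basis(g):
        raise PedigreeStructureError(
            "pedigree contains a loop; loop breaking is not supported"
        )


def _phenotype_of(ind, model: LinkageModel) -> str:
    aff = ind.affection
    if model.affected_only and aff == "unaffected":
        return "unknown"
    return aff


def _genotype_index_arrays(a: int) -> tuple[np.ndarray, ...]:
    """Per-ordered-genotype haplotype decompositions (paternal, maternal)."""
    H = 2 * a
    h1 = np.repeat(np.arange(H), H)
    h2 = np.tile(np.arange(H), H)
    return h1 // a, h1 % a, h2 // a, h2 % a  # d1, m1(0-based), d2, m2


def _unary_factor(ind, marker: MarkerData, model: LinkageModel) -> np.ndarray:
    """Phenotype penetrance x marker-observation indicator over ordered genotypes."""
    a = marker.n_alleles
    d1, m1, d2, m2 = _genotype_index_arrays(a)
    pen = np.asarray(model.penetrance)
    pheno = _phenotype_of(ind, model)
    if pheno == "affected":
        fac = pen[d1 + d2].astype(float)
    elif pheno == "unaffected":
        fac = 1.0 - pen[d1 + d2]
    else:
        fac = np.ones(len(d1))
    obs = marker.genotypes.get(ind.iid)
    if obs is not None:
        x, y = obs[0] - 1, obs[1] - 1
        fac = fac * (((m1 == x) & (m2 == y)) | ((m1 == y) & (m2 == x)))
    return fac


def _founder_prior(marker: MarkerData, model: LinkageModel) -> np.ndarray:
    a = marker.n_alleles
    q = model.disease_allele_freq
    hap = np.concatenate(
        [(1.0 - q) * np.asarray(marker.allele_freqs),
         q * np.asarray(marker.allele_freqs)]
    )
    return np.outer(hap, hap).ravel()


def _gamete_matrix(a: int, theta: float) -> np.ndarray:
    """T[g, h] = P(parent with ordered genotype g transmits haplotype h)."""
    H = 2 * a
    d1, m1, d2, m2 = _genotype_index_arrays(a)
    g = np.arange(H * H)
    T = np.zeros((H * H, H))
    np.add.at(T, (g, d1 * a + m1), (1 - theta) / 2)
    np.add.at(T, (g, d2 * a + m2), (1 - theta) / 2)
    np.add.at(T, (g, d1 * a + m2), theta / 2)
    np.add.at(T, (g, d2 * a + m1), theta / 2)
    return T


# ---------------------------------------------------------------------------
# Elston–Stewart peeling (variable elimination)
# ---------------------------------------------------------------------------

def _multiply_factors(vars1, arr1, vars2, arr2):
    all_vars = list(vars1) + [v for v in vars2 if v not in vars1]
    idx = {v: i for i, v in enumerate(all_vars)}

    def expand(vs, arr):
        shape = [1] * len(all_vars)
        order = sorted(range(len(vs)), key=lambda i: idx[vs[i]])
        arr = np.transpose(arr, order)
        for i, v in enumerate(sorted(vs, key=lambda v: idx[v])):
            shape[idx[v]] = arr.shape[i]
        return arr.reshape(shape)

    return all_vars, expand(vars1, arr1) * expand(vars2, arr2)


def _static_factors(
    ped: Pedigree, marker: MarkerData, model: LinkageModel
) -> list[tuple[list[str], np.ndarray]]:
    """Theta-independent factors: priors, penetrances, marker observations."""
    prior = _founder_prior(marker, model)
    factors = []
    for ind in ped.individuals.values():
        u = _unary_factor(ind, marker, model)
        if ind.is_founder:
            u = u * prior
        factors.append(([ind.iid], u))
    return factors


@lru_cache(maxsize=256)
def _transmission_halves(a: int, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Child factor P(gc | gf, gm) factorized into paternal x maternal halves:
    Fpat[gc, gf] = T[gf, pat_hap(gc)], Fmat[gc, gm] = T[gm, mat_hap(gc)]."""
    H = 2 * a
    n_g = H * H
    T = _gamete_matrix(a, theta)
    pat_hap = np.arange(n_g) // H
    mat_hap = np.arange(n_g) % H
    return T[:, pat_hap].T, T[:, mat_hap].T


def _transmission_factors(
    ped: Pedigree, a: int, theta: float
) -> list[tuple[list[str], np.ndarray]]:
    Fpat, Fmat = _transmission_halves(a, theta)
    factors: list[tuple[list[str], np.ndarray]] = []
    for ind in ped.individuals.values():
        if not ind.is_founder:
            factors.append(([ind.iid, ind.father], Fpat))
            factors.append(([ind.iid, ind.mother], Fmat))
    return factors


def _peel(
    variables: set[str], factors: list[tuple[list[str], np.ndarray]]
) -> float:
    """Eliminate all variables; return log10 of the normalizing constant."""
    log10_scale = 0.0
    remaining = set(variables)
    while remaining:
        # greedy: eliminate the variable whose merged factor is smallest
        def cost(v: str) -> int:
            union: set[str] = set()
            for vs, _ in factors:
                if v in vs:
                    union.update(vs)
            return len(union)

        var = min(sorted(remaining), key=cost)
        involved = [(vs, arr) for vs, arr in factors if var in vs]
        factors = [(vs, arr) for vs, arr in factors if var not in vs]
        mvars, marr = involved[0]
        for vs, arr in involved[1:]:
            mvars, marr = _multiply_factors(mvars, marr, vs, arr)
        axis = mvars.index(var)
        marr = marr.sum(axis=axis)
        mvars = [v for v in mvars if v != var]
        peak = marr.max() if marr.size else 0.0
        if peak <= 0.0:
            return -math.inf
        marr = marr / peak
        log10_scale += math.log10(peak)
        factors.append((mvars, marr))
        remaining.discard(var)

    value = 1.0
    for _, arr in factors:
        value *= float(arr) if arr.ndim == 0 else float(arr.ravel()[0])
    if value <= 0.0:
        return -math.inf
    return log10_scale + math.log10(value)


def pedigree_log_likelihood(
    ped: Pedigree,
    marker: MarkerData,
    model: LinkageModel,
    theta: float,
) -> float:
    """log10 likelihood of the pedigree data at recombination fraction theta.

    Returns ``-inf`` (Mendelian-impossible marker data) rather than raising.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValidationError("theta must be in [0, 0.5]")
    _check_no_loops(ped)
    factors = _static_factors(ped, marker, model) + _transmission_factors(
        ped, marker.n_alleles, theta
    )
    return _peel(set(ped.individuals), factors)


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_log_likelihood(
    ped: Pedigree,
    marker: MarkerData,
    model: LinkageModel,
    theta: float,
    max_members: int = 10,
) -> float:
    """Exact likelihood by enumeration over all joint ordered-haplotype states.

    Independent scalar re-derivation used as the verification oracle for
    :func:`pedigree_log_likelihood`; limited to small pedigrees.
    """
    if len(ped) > max_members:
        raise SizeError(f"{len(ped)} members > limit {max_members}")
    a = marker.n_alleles
    q = model.disease_allele_freq

    def hap_freq(d: int, m: int) -> float:
        return (q if d else 1.0 - q) * marker.allele_freqs[m - 1]

    def obs_weight(ind, state) -> float:
        d1, m1, d2, m2 = state
        w = 1.0
        pheno = _phenotype_of(ind, model)
        if pheno == "affected":
            w *= model.penetrance[d1 + d2]
        elif pheno == "unaffected":
            w *= 1.0 - model.penetrance[d1 + d2]
        obs = marker.genotypes.get(ind.iid)
        if obs is not None and sorted((m1, m2)) != sorted(obs):
            return 0.0
        return w

    def gamete_p(parent_state, d: int, m: int) -> float:
        d1, m1, d2, m2 = parent_state
        p = 0.0
        if (d, m) == (d1, m1):
            p += (1 - theta) / 2
        if (d, m) == (d2, m2):
            p += (1 - theta) / 2
        if (d, m) == (d1, m2):
            p += theta / 2
        if (d, m) == (d2, m1):
            p += theta / 2
        return p

    all_states = [
        (d1, m1, d2, m2)
        for d1 in (0, 1)
        for m1 in range(1, a + 1)
        for d2 in (0, 1)
        for m2 in range(1, a + 1)
    ]
    order = ped.topological_order()
    allowed = {
        ind.iid: [
            (s, obs_weight(ind, s)) for s in all_states if obs_weight(ind, s) > 0
        ]
        for ind in order
    }

    total = 0.0

    def recurse(i: int, assigned: dict, weight: float) -> None:
        nonlocal total
        if i == len(order):
            total += weight
            return
        ind = order[i]
        for state, w in allowed[ind.iid]:
            d1, m1, d2, m2 = state
            if ind.is_founder:
                contrib = hap_freq(d1, m1) * hap_freq(d2, m2) * w
            else:
                contrib = (
                    gamete_p(assigned[ind.father], d1, m1)
                    * gamete_p(assigned[ind.mother], d2, m2)
                    * w
                )
            if contrib == 0.0:
                continue
            assigned[ind.iid] = state
            recurse(i + 1, assigned, weight * contrib)
        assigned.pop(ind.iid, None)

    recurse(0, {}, 1.0)
    return math.log10(total) if total > 0 else -math.inf


# ---------------------------------------------------------------------------
# LOD curves
# ---------------------------------------------------------------------------

DEFAULT_THETA_GRID = np.round(np.arange(0.0, 0.501, 0.01), 2)


def lod_curve(
    ped: Pedigree,
    marker: MarkerData,
    model: LinkageModel | None = None,
    theta_grid: Sequence[float] | None = None,
) -> LodCurve:
    """LOD(theta) = log10 L(theta) - log10 L(0.5) over a theta grid.

    The grid must contain 0.5 (the null against which LOD is defined).
    """
    model = model or LinkageModel()
    thetas = np.asarray(
        DEFAULT_THETA_GRID if theta_grid is None else theta_grid, dtype=float
    )
    if 0.5 not in thetas:
        raise ValidationError("theta grid must include 0.5")
    if thetas.min() < 0 or thetas.max() > 0.5:
        raise ValidationError("theta grid must lie within [0, 0.5]")
    _check_no_loops(ped)
    static = _static_factors(ped, marker, model)
    ids = set(ped.individuals)

    def ll(theta: float) -> float:
        return _peel(
            ids, static + _transmission_factors(ped, marker.n_alleles, theta)
        )

    ll_half = ll(0.5)
    lods = np.empty_like(thetas)
    for i, th in enumerate(thetas):
        lods[i] = 0.0 if th == 0.5 else ll(float(th)) - ll_half
    imax = int(np.argmax(lods))
    return LodCurve(
        thetas=thetas,
        lod=lods,
        theta_max=float(thetas[imax]),
        lod_max=float(lods[imax]),
    )


def sum_lod_curves(curves: Sequence[LodCurve]) -> LodCurve:
    """Total LOD over independent families (shared theta grid required)."""
    if not curves:
        raise ValidationError("no curves to sum")
    thetas = curves[0].thetas
    for c in curves[1:]:
        if not np.array_equal(c.thetas, thetas):
            raise ValidationError("curves use different theta grids")
    lod = np.sum([c.lod for c in curves], axis=0)
    imax = int(np.argmax(lod))
    return LodCurve(thetas, lod, float(thetas[imax]), float(lod[imax]))


def write_lod_tsv(curves: Mapping[str, LodCurve], path: str) -> None:
    """TSV of theta vs per-family LOD plus the summed column."""
    names = list(curves)
    total = sum_lod_curves([curves[n] for n in names]) if len(names) > 1 else None
    with open(path, "w") as fh:
        header = ["theta"] + names + (["total"] if total else [])
        fh.write("\t".join(header) + "\n")
        thetas = curves[names[0]].thetas
        for i, th in enumerate(thetas):
            row = [f"{th:.2f}"] + [f"{curves[n].lod[i]:.4f}" for n in names]
            if total:
                row.append(f"{total.lod[i]:.4f}")
            fh.write("\t".join(row) + "\n")
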