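"""Exact enrichment and descriptive statistics for cohort screening results.

The headline numbers of a variant-screening study — "k in n carriers",
"significantly enriched versus a 38,722-individual reference panel",
"prevalence 1 in N" — all reduce to a handful of exact computations on
small integer tables: a one-sided Fisher test evaluated in log space (the
panel comparisons produce p-values far below float underflow), binomial
proportion intervals, and Welch's t for the reporter-assay comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

LN10 = math.log(10.0)


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table: rows are groups, columns carrier / non-carrier."""

    a: int  # group-1 carriers (e.g. cases)
    b: int  # group-1 non-carriers
    c: int  # group-2 carriers
    d: int  # group-2 non-carriers

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class FisherResult:
    p: float          # may underflow to 0.0; log10_p is always finite
    log10_p: float

    def __float__(self) -> float:
        return self.p


def _log_hypergeom_pmf(k: int, n: int, K: int, n_draw: int) -> float:
    """log P(X = k) for X ~ Hypergeom(N=n, K successes, n_draw draws)."""
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(n - K + 1) - gammaln(n_draw - k + 1) - gammaln(n - K - n_draw + k + 1)
        - (gammaln(n + 1) - gammaln(n_draw + 1) - gammaln(n - n_draw + 1))
    )


def fisher_exact_one_sided(table: TwoByTwo, exact: bool = False) -> FisherResult:
    """Upper-tail Fisher exact test: P(X >= a) given the table's margins.

    The direction tested is enrichment of carriers in the first group. The
    default path accumulates log hypergeometric probabilities, so p-values
    down to log10 p ~ -1e6 are representable; ``exact=True`` switches to
    rational arithmetic (suitable for small tables).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.n == 0:
        warnings.warn("all-zero 2x2 table; p = 1", stacklevel=2)
        return FisherResult(1.0, 0.0)
    n = table.n
    row1 = a + b
    col1 = a + c
    k_max = min(row1, col1)
    if exact:
        total = Fraction(0)
        denom = math.comb(n, row1)
        for k in range(a, k_max + 1):
            total += Fraction(
                math.comb(col1, k) * math.comb(n - col1, row1 - k), denom
            )
            if total > 1:
                total = Fraction(1)
                break
        p = min(total, Fraction(1))
        pf = float(p)
        return FisherResult(pf, math.log10(pf) if p > 0 else -math.inf)
    log_terms = [
        _log_hypergeom_pmf(k, n, col1, row1) for k in range(a, k_max + 1)
    ]
    if not log_terms:
        return FisherResult(1.0, 0.0)
    log_p = float(logsumexp(log_terms))
    log_p = min(log_p, 0.0)
    log10_p = log_p / LN10
    return FisherResult(math.exp(log_p), log10_p)


# ---------------------------------------------------------------------------
# Proportions, confidence intervals, prevalence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProportionCI:
    k: int
    n: int
    estimate_pct: float
    lo_pct: float
    hi_pct: float
    method: str
    level: float

    @property
    def display(self) -> str:
        return (
            f"{self.estimate_pct:.1f}% "
            f"(95% CI {self.lo_pct:.1f}-{self.hi_pct:.1f}, {self.method})"
        )


def _wilson_interval(k: int, n: int, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2)
    phat = k / n
    denom = 1 + z * z / n
    centre = phat + z * z / (2 * n)
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n))
    return ((centre - half) / denom, (centre + half) / denom)


def _clopper_pearson_interval(k: int, n: int, level: float) -> tuple[float, float]:
    alpha = 1 - level
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return (lo, hi)


def proportion_with_ci(
    k: int, n: int, method: str = "wilson", level: float = 0.95
) -> ProportionCI:
    """Point estimate (as a percentage) with a binomial confidence interval.

    ``method`` is "wilson" (score interval, default) or "clopper_pearson".
    The estimate displays at one decimal; raw bounds are kept unrounded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    if method == "wilson":
        lo, hi = _wilson_interval(k, n, level)
    elif method == "clopper_pearson":
        lo, hi = _clopper_pearson_interval(k, n, level)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return ProportionCI(k, n, 100.0 * k / n, 100.0 * lo, 100.0 * hi, method, level)


def _round_sig(x: float, sig: int = 3) -> int:
    if x <= 0:
        raise ValueError("positive value required")
    exp = math.floor(math.log10(x))
    factor = 10 ** (exp - sig + 1)
    return int(round(x / factor) * factor)


@dataclass(frozen=True)
class PrevalenceEstimate:
    k: int
    n: int
    one_in: int | None          # None when k = 0
    ci_one_in: tuple[int | None, int]  # (widest "1 in", narrowest "1 in")
    method: str

    @property
    def display(self) -> str:
        point = f"1/{self.one_in:,}" if self.one_in else "undefined"
        lo = f"1/{self.ci_one_in[1]:,}"
        hi = f"1/{self.ci_one_in[0]:,}" if self.ci_one_in[0] else "1/inf"
        return f"{point} (95% CI {lo} to {hi}, {self.method})"


def prevalence_estimate(
    k_carriers: int, n_panel: int, ci_method: str = "wilson", level: float = 0.95
) -> PrevalenceEstimate:
    """Carrier prevalence as "1 in N", N rounded to 3 significant figures.

    The confidence interval is the chosen proportion interval inverted;
    which interval the source screening studies used is generally
    unreported, so the method is carried in the output.
    """
    if n_panel < 1:
        raise ValueError("panel size must be >= 1")
    if k_carriers < 0:
        raise ValueError("negative carrier count")
    ci = proportion_with_ci(k_carriers, n_panel, method=ci_method, level=level)
    hi_n = _round_sig(100.0 / ci.lo_pct) if ci.lo_pct > 0 else None
    lo_n = _round_sig(100.0 / ci.hi_pct) if ci.hi_pct > 0 else 1
    if k_carriers == 0:
        return PrevalenceEstimate(k_carriers, n_panel, None, (hi_n, lo_n), ci_method)
    return PrevalenceEstimate(
        k_carriers,
        n_panel,
        _round_sig(n_panel / k_carriers),
        (hi_n, lo_n),
        ci_method,
    )


# ---------------------------------------------------------------------------
# Welch's t
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_t_test(xs, ys) -> WelchResult:
    """Two-sided Welch's t test with Welch–Satterthwaite degrees of freedom."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("each sample needs >= 2 observations")
    vx, vy = xs.var(ddof=1), ys.var(ddof=1)
    if vx == 0 and vy == 0:
        if xs.mean() == ys.mean():
            return WelchResult(0.0, float(len(xs) + len(ys) - 2), 1.0)
        warnings.warn("zero variance in both samples with differing means", stacklevel=2)
        return WelchResult(math.inf if xs.mean() > ys.mean() else -math.inf,
                           float(len(xs) + len(ys) - 2), 0.0)
    res = stats.ttest_ind(xs, ys, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


# ---------------------------------------------------------------------------
# Diagnostic yield tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortCounts:
    """Carrier and other-diagnosis counts in a cohort and its subgroups.

    ``subgroups`` maps a label to (carriers, subgroup size); the whole-cohort
    row is included under the label "all".
    """

    n_total: int
    n_variant: int
    n_other_solved: int
    subgroups: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.n_variant + self.n_other_solved > self.n_total:
            raise ValueError("carriers + other diagnoses exceed cohort size")
        for label, (k, n) in self.subgroups.items():
            if not 0 <= k <= n:
                raise ValueError(f"subgroup {label}: {k}/{n} inconsistent")


def diagnostic_yield(counts: CohortCounts, ci_method: str = "wilson"):
    """Percentage of carriers per subgroup with confidence intervals.

    Returns {label: ProportionCI}; empty subgroups are omitted with a warning.
    """
    rows: dict[str, ProportionCI] = {}
    for label, (k, n) in counts.subgroups.items():
        if n == 0:
            warnings.warn(f"subgroup {label!r} is empty; omitted", stacklevel=2)
            continue
        rows[label] = proportion_with_ci(k, n, method=ci_method)
    return rows
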