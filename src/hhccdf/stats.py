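"""Per-marker association statistics.

* :func:`hccdf_tail` — hypergeometric complementary cumulative tail
  ``P(X > k)`` for ``X ~ Hypergeometric(N, K, d)``, the per-boundary P value.
* :func:`hh_ccdf` — geometric mean of the ``n - 1`` per-boundary tails for a
  marker with ``n`` genotype categories.
* :func:`ha_coefficient` — hierarchical association coefficient, a [0, 1]
  measure built from boundary subset sums through ``f(t) = y ln(t) - t``.
* :func:`f_test` — one-way fixed-effects ANOVA of phenotype on genotype
  class, the linear-model comparator.
* :func:`normalize_minmax` — affine rescaling onto [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .categorize import (
    MarkerGenotypes,
    PhenotypeVector,
    boundary_counts,
    boundary_sums,
    stratify,
)
from .exceptions import (
    DegenerateSpread,
    InvalidCounts,
    NonPositiveInput,
)

__all__ = [
    "TailProbability",
    "AnovaDecomposition",
    "HaResult",
    "hccdf_tail",
    "hh_ccdf",
    "hh_ccdf_from_stratification",
    "ha_coefficient",
    "ha_from_stratification",
    "f_test",
    "f_test_from_stratification",
    "normalize_minmax",
]

# Above this population size exact big-integer accumulation gets needlessly
# slow; scipy's log-gamma survival function takes over.
_EXACT_N_LIMIT = 1000


@dataclass(frozen=True)
class TailProbability:
    value: float

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"tail probability {self.value} outside [0, 1]")

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class AnovaDecomposition:
    """One-way ANOVA pieces: y_ij = mu + alpha_i + eps_ij."""

    grand_mean: float
    group_effects: dict
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    p: float


@dataclass(frozen=True)
class HaResult:
    value: float
    per_boundary_ratios: tuple


def _exact_tail(N: int, K: int, d: int, k: int) -> float:
    """1 - sum_{i=0}^{k} C(K,i) C(N-K,d-i) / C(N,d) in exact integers.

    Terms follow the multiplicative recurrence
    t_{i+1} = t_i (K-i)(d-i) / ((i+1)(N-K-d+i+1)); each step's division is
    exact, so no rationals are needed.
    """
    denom = math.comb(N, d)
    lo = max(0, K + d - N)
    if k < lo:
        return 1.0
    acc = 0
    t = math.comb(K, lo) * math.comb(N - K, d - lo)
    acc += t
    for i in range(lo, min(k, K, d)):
        t = t * (K - i) * (d - i) // ((i + 1) * (N - K - d + i + 1))
        acc += t
    if acc >= denom:
        return 0.0
    return float((denom - acc) / denom)


def hccdf_tail(N: int, K: int, d: int, k: int) -> TailProbability:
    """Upper tail P(X > k) of the hypergeometric law with population ``N``,
    ``K`` successes and ``d`` draws.

    For ``N`` up to 1000 the sum is accumulated in exact integer arithmetic;
    beyond that a log-gamma survival function is used, avoiding binomial
    overflow at any realistic population size.
    """
    if not (isinstance(N, (int, np.integer)) and isinstance(K, (int, np.integer))
            and isinstance(d, (int, np.integer)) and isinstance(k, (int, np.integer))):
        raise InvalidCounts("N, K, d, k must be integers")
    if not (0 <= k <= d <= N and 0 <= K <= N):
        raise InvalidCounts(f"invalid hypergeometric counts N={N} K={K} d={d} k={k}")
    if N <= _EXACT_N_LIMIT:
        p = _exact_tail(int(N), int(K), int(d), int(k))
    else:
        p = float(sps.hypergeom.sf(k, N, K, d))
        p = min(max(p, 0.0), 1.0)
    return TailProbability(p)


def hh_ccdf(pheno: PhenotypeVector, geno: MarkerGenotypes) -> TailProbability:
    """Geometric mean of the per-boundary hypergeometric tails.

    Combined in log space; an exact-zero factor (a boundary whose observed
    ``s1`` attains the top categorization, ``k = d``) makes the result exactly
    0 — perfect association is not smoothed away.
    """
    return hh_ccdf_from_stratification(stratify(pheno, geno))


def hh_ccdf_from_stratification(strat) -> TailProbability:
    """:func:`hh_ccdf` on an already-built stratification."""
    counts = boundary_counts(strat)
    logs = []
    for c in counts:
        p = hccdf_tail(c.N, c.K, c.d, c.k).value
        if p == 0.0:
            return TailProbability(0.0)
        logs.append(math.log(p))
    if len(logs) == 1:  # binary marker: the single tail, exactly
        return TailProbability(p)
    return TailProbability(math.exp(sum(logs) / len(logs)))


def ha_coefficient(pheno: PhenotypeVector, geno: MarkerGenotypes) -> HaResult:
    """Hierarchical association coefficient.

    Per boundary the ratio ``(f(obs) - f(btm)) / (f(top) - f(btm))`` with
    ``f(t) = y ln(t) - t`` locates the observed ``s1`` sum between the
    bottom-categorization and top-categorization extremes; the coefficient is
    the geometric mean of the ratios.  Requires positive phenotype mass —
    negative trait values or a non-positive subset sum are refused rather
    than silently rescaled (use min-max normalization first).
    """
    return ha_from_stratification(stratify(pheno, geno))


def ha_from_stratification(strat) -> HaResult:
    """:func:`ha_coefficient` on an already-built stratification."""
    if float(np.min(strat.all_values())) < 0.0:
        raise NonPositiveInput(
            "HA coefficient requires non-negative trait values; "
            "min-max normalize the phenotype first"
        )
    sums = boundary_sums(strat)
    ratios = []
    for s in sums:
        if min(s.y, s.obs, s.top, s.btm) <= 0.0:
            raise NonPositiveInput(
                f"non-positive subset sum at boundary {s.boundary_index}"
            )
        if s.top == s.btm:
            raise DegenerateSpread(
                f"top and bottom sums coincide at boundary {s.boundary_index}"
            )

        def f(t: float, y: float = s.y) -> float:
            return y * math.log(t) - t

        ratios.append((f(s.obs) - f(s.btm)) / (f(s.top) - f(s.btm)))
    value = float(np.exp(np.mean(np.log(ratios)))) if min(ratios) > 0.0 else 0.0
    return HaResult(value=value, per_boundary_ratios=tuple(ratios))


def f_test(pheno: PhenotypeVector, geno: MarkerGenotypes) -> AnovaDecomposition:
    """One-way fixed-effects ANOVA of the trait on genotype class."""
    return f_test_from_stratification(stratify(pheno, geno))


def f_test_from_stratification(strat) -> AnovaDecomposition:
    """:func:`f_test` on an already-built stratification."""
    if strat.n < 2:
        raise DegenerateSpread("F test needs at least two genotype classes")
    if strat.N - strat.n < 1:
        raise DegenerateSpread("F test needs at least one within-group df")
    values = strat.all_values()
    grand = float(values.mean())
    ss_between = sum(g.size * (g.mean - grand) ** 2 for g in strat.groups)
    ss_within = sum(
        float(((g.member_values - g.mean) ** 2).sum()) for g in strat.groups
    )
    df_b = strat.n - 1
    df_w = strat.N - strat.n
    if ss_within == 0.0 and ss_between == 0.0:
        raise DegenerateSpread("constant phenotype: F undefined")
    if ss_within == 0.0:
        F = math.inf
        p = 0.0
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(F, df_b, df_w))
    return AnovaDecomposition(
        grand_mean=grand,
        group_effects={g.label: g.mean - grand for g in strat.groups},
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        df_between=df_b,
        df_within=df_w,
        F=float(F),
        p=p,
    )


def normalize_minmax(values) -> np.ndarray:
    """Affine map onto [0, 1]: z_i = (x_i - min x) / (max x - min x)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateSpread("min-max normalization needs at least two values")
    lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
    if not hi > lo:
        raise DegenerateSpread("constant input: min equals max")
    return (x - lo) / (hi - lo)
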