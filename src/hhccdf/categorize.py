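"""Hierarchical stratification of genotype categories.

A marker splits the population into genotype classes (opaque categorical
labels such as ``0/1/2`` or ``-1/0/1``).  Ordering those classes by ascending
mean phenotype gives the *hierarchical stratification*; each of the ``n - 1``
gaps between adjacent classes defines a *hierarchical binary categorization*
in which the right-hand (higher-mean) subset is called ``s1``.

Per boundary this module derives the quantities every downstream statistic
consumes:

* counts ``(N, d, K, k)`` — population size, size of ``s1``, and the size of
  the multiset intersection between the ``d`` largest trait values and the
  trait values observed in ``s1`` (ties matched up to multiplicity);
* sums ``(y, obs, top, btm)`` — total trait sum, observed ``s1`` sum, and the
  sums of the ``d`` largest / ``d`` smallest trait values.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateMarker, EmptyJoin

__all__ = [
    "PhenotypeVector",
    "MarkerGenotypes",
    "CategoryGroup",
    "HierarchicalStratification",
    "BoundaryCounts",
    "BoundarySums",
    "stratify",
    "boundary_counts",
    "boundary_sums",
]


@dataclass(frozen=True)
class PhenotypeVector:
    """Quantitative trait values keyed by individual identifiers."""

    ids: tuple
    values: np.ndarray

    def __init__(self, ids: Sequence, values: Sequence[float]):
        ids = tuple(str(i) for i in ids)
        values = np.asarray(values, dtype=float)
        if len(ids) != len(values):
            raise ValueError("ids and values must have equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("trait values must all be finite")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class MarkerGenotypes:
    """Categorical genotype labels for one marker.

    Labels are opaque: ``{0, 1, 2}`` and ``{-1, 0, 1}`` are equally valid and
    never interpreted as dosages.  A label equal to ``missing_sentinel`` marks
    a missing call.
    """

    ids: tuple
    labels: tuple
    missing_sentinel: object = None

    def __init__(self, ids: Sequence, labels: Sequence, missing_sentinel=None):
        ids = tuple(str(i) for i in ids)
        labels = tuple(labels)
        if len(ids) != len(labels):
            raise ValueError("ids and labels must have equal length")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "missing_sentinel", missing_sentinel)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class CategoryGroup:
    """One genotype class: its label, member trait values, and their mean."""

    label: object
    member_values: np.ndarray
    mean: float

    @property
    def size(self) -> int:
        return len(self.member_values)


@dataclass(frozen=True)
class HierarchicalStratification:
    """Genotype classes sorted ascending by class mean.

    ``n`` is the number of classes, ``N`` the number of retained individuals,
    and there are ``n - 1`` categorical boundaries between adjacent classes.
    """

    groups: tuple
    n: int = field(init=False)
    N: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "n", len(self.groups))
        object.__setattr__(self, "N", sum(g.size for g in self.groups))

    @property
    def n_boundaries(self) -> int:
        return self.n - 1

    def all_values(self) -> np.ndarray:
        return np.concatenate([g.member_values for g in self.groups])

    def s1_values(self, boundary_index: int) -> np.ndarray:
        """Trait values of the right subset at boundary ``x`` (1-based)."""
        if not 1 <= boundary_index <= self.n_boundaries:
            raise ValueError(f"boundary index {boundary_index} out of range")
        return np.concatenate(
            [g.member_values for g in self.groups[boundary_index:]]
        )


@dataclass(frozen=True)
class BoundaryCounts:
    """The ``(N, d, K, k)`` quadruple for one hierarchical binary
    categorization; feeds the hypergeometric tail."""

    boundary_index: int
    N: int
    d: int
    K: int
    k: int

    def __post_init__(self):
        if not (0 <= self.k <= self.d <= self.N) or self.K != self.d:
            raise ValueError(f"inconsistent boundary counts: {self}")


@dataclass(frozen=True)
class BoundarySums:
    """The ``(y, obs, top, btm)`` subset sums for one boundary; feed the HA
    coefficient."""

    boundary_index: int
    y: float
    obs: float
    top: float
    btm: float


def _join(pheno: PhenotypeVector, geno: MarkerGenotypes):
    """Inner-join phenotype and genotype on individual id, dropping missing
    genotype calls and non-finite phenotypes."""
    pheno_map = dict(zip(pheno.ids, pheno.values))
    vals, labs = [], []
    for ind, lab in zip(geno.ids, geno.labels):
        if lab == geno.missing_sentinel:
            continue
        v = pheno_map.get(ind)
        if v is None or not np.isfinite(v):
            continue
        vals.append(v)
        labs.append(lab)
    if not set(pheno.ids) & set(geno.ids):
        raise EmptyJoin("no shared individual ids between phenotype and genotypes")
    if not vals:
        raise DegenerateMarker("all genotype calls missing for this marker")
    return np.asarray(vals, dtype=float), labs


def stratify(pheno: PhenotypeVector, geno: MarkerGenotypes) -> HierarchicalStratification:
    """Build the hierarchical stratification for one marker.

    Individuals present in both inputs, with a non-missing genotype and a
    finite phenotype, are grouped by genotype label; groups are ordered by
    ascending mean trait value.  Mean ties are broken by the label's text
    representation so the order is deterministic.
    """
    values, labels = _join(pheno, geno)
    by_label: dict = {}
    for v, lab in zip(values, labels):
        by_label.setdefault(lab, []).append(v)
    groups = [
        CategoryGroup(label=lab, member_values=np.asarray(vs, dtype=float),
                      mean=float(np.mean(vs)))
        for lab, vs in by_label.items()
    ]
    groups.sort(key=lambda g: (g.mean, str(g.label)))
    return HierarchicalStratification(groups=tuple(groups))


def _require_boundaries(strat: HierarchicalStratification) -> None:
    if strat.n < 2:
        raise DegenerateMarker(
            "marker has a single genotype category; no boundary exists"
        )


def _multiset_intersection_size(top_d: np.ndarray, s1: np.ndarray) -> int:
    """|top-d multiset ∩ observed-s1 multiset|, ties matched up to
    multiplicity.  Equals the maximum intersection over all tie-consistent
    top categorizations."""
    ctop = Counter(top_d.tolist())
    cs1 = Counter(s1.tolist())
    return sum(min(c, cs1[v]) for v, c in ctop.items() if v in cs1)


def boundary_counts(strat: HierarchicalStratification) -> list[BoundaryCounts]:
    """Per-boundary ``(N, d, K, k)``.

    At boundary ``x`` the right subset ``s1`` is the union of groups strictly
    right of the boundary; ``d = K = |s1|``; ``k`` is the multiset
    intersection between the ``d`` largest trait values in the population and
    the trait values observed in ``s1``.
    """
    _require_boundaries(strat)
    values_desc = np.sort(strat.all_values())[::-1]
    out = []
    for x in range(1, strat.n):
        s1 = strat.s1_values(x)
        d = len(s1)
        k = _multiset_intersection_size(values_desc[:d], s1)
        out.append(BoundaryCounts(boundary_index=x, N=strat.N, d=d, K=d, k=k))
    return out


def boundary_sums(strat: HierarchicalStratification) -> list[BoundarySums]:
    """Per-boundary ``(y, obs, top, btm)`` subset sums.

    ``top``/``btm`` are the sums of the ``d`` largest / smallest trait values,
    i.e. the ``s1`` sums under the top and bottom categorizations; ``obs`` is
    the observed ``s1`` sum.
    """
    _require_boundaries(strat)
    values_asc = np.sort(strat.all_values())
    y = float(values_asc.sum())
    out = []
    for x in range(1, strat.n):
        s1 = strat.s1_values(x)
        d = len(s1)
        out.append(
            BoundarySums(
                boundary_index=x,
                y=y,
                obs=float(s1.sum()),
                top=float(values_asc[-d:].sum()),
                btm=float(values_asc[:d].sum()),
            )
        )
    return out
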