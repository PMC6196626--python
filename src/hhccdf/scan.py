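"""Genome scan: apply the association statistics across a marker matrix.

The central object is :class:`MarkerAssociationScan`, a scikit-learn style
estimator: ``fit(X, y)`` takes a genotype matrix ``X`` (individuals x
markers, categorical labels) and a phenotype vector ``y`` and computes one
row of statistics per marker, exposed as ``results_`` plus per-method fitted
arrays.  :func:`scan` is the functional wrapper used by the CLI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import __version__
from .categorize import MarkerGenotypes, PhenotypeVector, stratify
from .exceptions import (
    DegenerateMarker,
    DegenerateSpread,
    DuplicateId,
    EmptyJoin,
    NonPositiveInput,
)
from .stats import (
    f_test_from_stratification,
    ha_from_stratification,
    hh_ccdf_from_stratification,
    normalize_minmax,
)

__all__ = [
    "GenotypeMatrix",
    "MarkerAssociationScan",
    "scan",
    "neg_log10",
    "normalize_scores",
    "write_scan_tsv",
]

METHODS = ("hhccdf", "ftest", "ha")

#: default floor under the -log10 transform; an exact-zero P value maps to 300
DEFAULT_P_FLOOR = 1e-300


@dataclass(frozen=True)
class GenotypeMatrix:
    """Rectangular table of categorical genotype labels.

    Rows are individuals, columns are markers; labels are opaque categories
    (``0/1/2`` and ``-1/0/1`` both valid).  ``missing_sentinel`` marks
    missing calls.
    """

    ids: tuple
    markers: tuple
    labels: np.ndarray  # object array, shape (n_individuals, n_markers)
    missing_sentinel: object = None

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=object)
        if labels.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"label table shape {labels.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.markers)} markers"
            )
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateId("duplicate individual ids")
        if len(set(self.markers)) != len(self.markers):
            raise DuplicateId("duplicate marker ids")
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "markers", tuple(str(m) for m in self.markers))
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def marker(self, j: int) -> MarkerGenotypes:
        """Genotype calls for the ``j``-th marker column."""
        return MarkerGenotypes(
            ids=self.ids,
            labels=self.labels[:, j].tolist(),
            missing_sentinel=self.missing_sentinel,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, missing_sentinel=None) -> "GenotypeMatrix":
        return cls(
            ids=tuple(df.index.astype(str)),
            markers=tuple(df.columns.astype(str)),
            labels=df.to_numpy(dtype=object),
            missing_sentinel=missing_sentinel,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.labels, index=list(self.ids),
                            columns=list(self.markers))


def neg_log10(p: float, floor: float = DEFAULT_P_FLOOR) -> float:
    """-log10(max(p, floor)); the floor keeps exact-zero P values plottable."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    return float(-np.log10(max(float(p), floor)))


def _resolve_ha_phenotype(values: np.ndarray, ha_normalize) -> np.ndarray:
    """Phenotype used for the HA coefficient.

    ``True`` forces min-max normalization; ``False`` passes values through
    (HA then refuses negatives itself); ``"auto"`` normalizes only when
    non-positive values are present, with a warning.
    """
    if ha_normalize is True:
        return normalize_minmax(values)
    if ha_normalize == "auto" and float(np.min(values)) <= 0.0:
        warnings.warn(
            "phenotype contains non-positive values; min-max normalizing "
            "to [0, 1] for the HA coefficient",
            UserWarning,
            stacklevel=3,
        )
        return normalize_minmax(values)
    return values


class MarkerAssociationScan(BaseEstimator):
    """Per-marker association scan over a categorical genotype matrix.

    Parameters
    ----------
    methods : sequence of {"hhccdf", "ftest", "ha"}
        Statistics to compute per marker.
    missing_sentinel : object, default None
        Genotype label treated as a missing call.
    ha_normalize : {"auto", True, False}, default "auto"
        Whether the phenotype is min-max normalized onto [0, 1] before the
        HA coefficient (which needs positive phenotype mass).
    p_floor : float, default 1e-300
        Floor applied under the -log10 transform of P values.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per marker: category count, retained N, statistics,
        -log10 P columns and a status flag (``ok`` / ``degenerate``).
    hh_pvalues_, f_pvalues_, f_statistic_, ha_values_ : ndarray
        Per-marker arrays (NaN where undefined), present for the requested
        methods.

    Examples
    --------
    >>> from hhccdf.datasets import load_worked_example
    >>> geno, pheno = load_worked_example()
    >>> est = MarkerAssociationScan(methods=("hhccdf",))
    >>> round(est.fit(geno.to_dataframe(), pheno.values).hh_pvalues_[0], 3)
    0.059
    """

    def __init__(self, methods: Sequence[str] = METHODS, missing_sentinel=None,
                 ha_normalize="auto", p_floor: float = DEFAULT_P_FLOOR):
        self.methods = methods
        self.missing_sentinel = missing_sentinel
        self.ha_normalize = ha_normalize
        self.p_floor = p_floor

    def _validate(self, X, y):
        methods = tuple(self.methods)
        if not methods:
            raise ValueError("methods must be nonempty")
        unknown = set(methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if isinstance(X, GenotypeMatrix):
            geno = X
        elif isinstance(X, pd.DataFrame):
            geno = GenotypeMatrix.from_dataframe(X, self.missing_sentinel)
        else:
            arr = np.asarray(X, dtype=object)
            if arr.ndim != 2:
                raise ValueError("X must be a 2D individuals x markers table")
            geno = GenotypeMatrix(
                ids=tuple(str(i) for i in range(arr.shape[0])),
                markers=tuple(f"m{j}" for j in range(arr.shape[1])),
                labels=arr,
                missing_sentinel=self.missing_sentinel,
            )
        if isinstance(y, PhenotypeVector):
            pheno = y
        elif isinstance(y, pd.Series):
            pheno = PhenotypeVector(ids=y.index.astype(str), values=y.to_numpy())
        else:
            yarr = np.asarray(y, dtype=float).ravel()
            if len(yarr) != len(geno.ids):
                raise ValueError(
                    f"y has {len(yarr)} values for {len(geno.ids)} individuals"
                )
            pheno = PhenotypeVector(ids=geno.ids, values=yarr)
        if not set(geno.ids) & set(pheno.ids):
            raise EmptyJoin("genotypes and phenotype share no individual ids")
        return geno, pheno, methods

    def fit(self, X, y):
        """Compute the per-marker statistics.

        ``X``: GenotypeMatrix, DataFrame (index = individual ids) or 2D
        array-like; ``y``: PhenotypeVector, Series (index = individual ids)
        or 1D array aligned with ``X``'s rows.
        """
        geno, pheno, methods = self._validate(X, y)
        want_ha = "ha" in methods
        ha_pheno = None
        if want_ha:
            shared = [i for i in pheno.ids if i in set(geno.ids)]
            vmap = dict(zip(pheno.ids, pheno.values))
            shared_vals = np.array([vmap[i] for i in shared])
            ha_vals = _resolve_ha_phenotype(shared_vals, self.ha_normalize)
            ha_pheno = PhenotypeVector(ids=shared, values=ha_vals)

        rows = []
        for j, marker_id in enumerate(geno.markers):
            mg = geno.marker(j)
            row = {"marker": marker_id, "status": "ok",
                   "n_categories": np.nan, "N_used": np.nan}
            try:
                strat = stratify(pheno, mg)
                row["n_categories"] = strat.n
                row["N_used"] = strat.N
                if strat.n < 2:
                    raise DegenerateMarker("single category")
            except DegenerateMarker:
                row["status"] = "degenerate"
                rows.append(row)
                continue
            if "hhccdf" in methods:
                p = hh_ccdf_from_stratification(strat).value
                row["hh_ccdf_p"] = p
                row["hh_ccdf_neglog10"] = neg_log10(p, self.p_floor)
            if "ftest" in methods:
                try:
                    an = f_test_from_stratification(strat)
                    row["f_stat"] = an.F
                    row["f_p"] = an.p
                    row["f_neglog10"] = neg_log10(an.p, self.p_floor)
                except DegenerateSpread:
                    pass
            if want_ha:
                try:
                    ha_strat = stratify(ha_pheno, mg)
                    row["ha"] = ha_from_stratification(ha_strat).value
                except (NonPositiveInput, DegenerateSpread):
                    pass
            rows.append(row)

        columns = ["marker", "n_categories", "N_used", "status"]
        if "hhccdf" in methods:
            columns += ["hh_ccdf_p", "hh_ccdf_neglog10"]
        if "ftest" in methods:
            columns += ["f_stat", "f_p", "f_neglog10"]
        if want_ha:
            columns += ["ha"]
        res = pd.DataFrame(rows).reindex(columns=columns)
        self.results_ = res
        self.n_features_in_ = len(geno.markers)
        self.feature_names_in_ = np.asarray(geno.markers, dtype=object)
        if "hhccdf" in methods:
            self.hh_pvalues_ = res["hh_ccdf_p"].to_numpy(dtype=float)
        if "ftest" in methods:
            self.f_pvalues_ = res["f_p"].to_numpy(dtype=float)
            self.f_statistic_ = res["f_stat"].to_numpy(dtype=float)
        if want_ha:
            self.ha_values_ = res["ha"].to_numpy(dtype=float)
        return self


def scan(geno: GenotypeMatrix, pheno: PhenotypeVector,
         methods: Iterable[str] = METHODS, ha_normalize="auto",
         p_floor: float = DEFAULT_P_FLOOR) -> pd.DataFrame:
    """Run the association scan and return the tidy results table."""
    est = MarkerAssociationScan(
        methods=tuple(methods), missing_sentinel=geno.missing_sentinel,
        ha_normalize=ha_normalize, p_floor=p_floor,
    )
    return est.fit(geno, pheno).results_


def normalize_scores(result: pd.DataFrame, column: str) -> pd.DataFrame:
    """Add ``<column>_norm``, the min-max normalized score column.

    NA rows are preserved; normalization uses the observed min/max of the
    non-NA entries.  Used to overlay scores from different methods on a
    common [0, 1] scale.
    """
    if column not in result.columns:
        raise KeyError(column)
    col = result[column].to_numpy(dtype=float)
    mask = np.isfinite(col)
    if mask.sum() < 2:
        raise DegenerateSpread(f"column {column!r} has fewer than 2 finite values")
    out = result.copy()
    normed = np.full_like(col, np.nan)
    normed[mask] = normalize_minmax(col[mask])
    out[column + "_norm"] = normed
    return out


def write_scan_tsv(result: pd.DataFrame, path, options: dict | None = None) -> None:
    """Write the results table as TSV with a ``#``-prefixed metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# hhccdf {__version__} scan results\n")
        for key, val in (options or {}).items():
            fh.write(f"# {key}: {val}\n")
        result.to_csv(fh, sep="\t", index=False, float_format="%.6g")
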