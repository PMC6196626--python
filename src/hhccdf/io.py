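"""Delimited-table readers and writers.

Genotype matrices and phenotype vectors travel as plain TSV/CSV (delimiter
auto-detected).  Genotype labels are preserved verbatim as text categories,
so ``0/1/2`` and ``-1/0/1`` codings — or any other labels — pass through
unchanged; VCF/PLINK ingestion is deliberately out of scope because the
inputs are categorical score matrices, not variant calls.
"""

from __future__ import annotations

import csv

import numpy as np

from .categorize import PhenotypeVector
from .exceptions import FormatError
from .scan import GenotypeMatrix

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "write_genotypes",
    "write_phenotypes",
]


def _read_rows(path) -> tuple[list[list[str]], str]:
    with open(path, newline="") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delim = "\t" if "\t" in lines[0] else ","
    rows = [[cell.strip() for cell in row] for row in csv.reader(lines, delimiter=delim)]
    return rows, delim


def read_genotypes(path, transpose: bool = False,
                   missing_sentinel: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from delimited text.

    Layout: header row of marker ids (first cell is a corner label), one row
    per individual with its id in the first column.  With ``transpose=True``
    the file is markers-as-rows and is flipped after reading.  Cells equal to
    ``missing_sentinel`` become missing calls.
    """
    rows, _ = _read_rows(path)
    if len(rows) < 2 or len(rows[0]) < 2:
        raise FormatError(f"{path}: need a header row and at least one data row")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: row {i + 1} has {len(row)} fields, expected {width}"
            )
    col_ids = tuple(rows[0][1:])
    row_ids = tuple(r[0] for r in rows[1:])
    table = np.array([r[1:] for r in rows[1:]], dtype=object)
    if transpose:
        row_ids, col_ids = col_ids, row_ids
        table = table.T
    return GenotypeMatrix(
        ids=row_ids,
        markers=col_ids,
        labels=table,
        missing_sentinel=missing_sentinel,
    )


def read_phenotypes(path) -> PhenotypeVector:
    """Read an (id, value) two-column table; a header row is optional and
    detected by a non-numeric second field."""
    rows, _ = _read_rows(path)
    start = 0
    if len(rows[0]) >= 2:
        try:
            float(rows[0][1])
        except ValueError:
            start = 1
    ids, values = [], []
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 2:
            raise FormatError(f"{path}: row {i} has fewer than 2 fields")
        try:
            values.append(float(row[1]))
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric phenotype {row[1]!r} on row {i}"
            ) from exc
        ids.append(row[0])
    if not ids:
        raise FormatError(f"{path}: no phenotype records")
    try:
        return PhenotypeVector(ids=ids, values=values)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_genotypes(geno: GenotypeMatrix, path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["id", *geno.markers])
        sentinel = geno.missing_sentinel
        for ind, row in zip(geno.ids, geno.labels):
            w.writerow([ind] + [sentinel if c == sentinel else c for c in row])


def write_phenotypes(pheno: PhenotypeVector, path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["id", "value"])
        for ind, val in zip(pheno.ids, pheno.values):
            w.writerow([ind, format(val, "g")])
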