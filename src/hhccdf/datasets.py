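"""Bundled worked example: 20 individuals, one triallelic marker.

The dataset pairs a categorical marker (scores 0/1/2) with a quantitative
trait.  Its category means sort the scores as 0 < 2 < 1, and the two
boundary tails combine to an HH-CCDF P value of 0.059 — the package's
reference calculation (see ``hhccdf demo``).
"""

from __future__ import annotations

from .categorize import PhenotypeVector
from .scan import GenotypeMatrix

#: (individual id, marker score, trait value)
WORKED_EXAMPLE = (
    ("ID 1", 1, 140.0),
    ("ID 2", 1, 122.0),
    ("ID 3", 2, 116.0),
    ("ID 4", 1, 114.0),
    ("ID 5", 1, 112.0),
    ("ID 6", 2, 108.0),
    ("ID 7", 2, 108.0),
    ("ID 8", 0, 105.0),
    ("ID 9", 1, 105.0),
    ("ID 10", 1, 102.0),
    ("ID 11", 0, 101.0),
    ("ID 12", 0, 99.0),
    ("ID 13", 0, 98.0),
    ("ID 14", 2, 97.0),
    ("ID 15", 0, 95.0),
    ("ID 16", 1, 94.0),
    ("ID 17", 2, 91.0),
    ("ID 18", 2, 86.0),
    ("ID 19", 1, 84.0),
    ("ID 20", 0, 76.0),
)


def load_worked_example() -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Return the 20-individual example as a single-marker genotype matrix
    and its phenotype vector."""
    ids = [r[0] for r in WORKED_EXAMPLE]
    geno = GenotypeMatrix(
        ids=tuple(ids),
        markers=("marker1",),
        labels=[[r[1]] for r in WORKED_EXAMPLE],
    )
    pheno = PhenotypeVector(ids=ids, values=[r[2] for r in WORKED_EXAMPLE])
    return geno, pheno
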