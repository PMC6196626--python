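"""Triangle-pattern QTL signal simulator.

The generator emulates a genotype matrix whose association signal strength
varies along the genome in a controlled way.  Three marker blocks each carry
a pair of vertically symmetric triangles: within a block, columns near the
block centre have their top rows forced to score 0 and bottom rows forced to
score 2, with the forced depth tapering linearly to zero at the block edges.
Everything else is i.i.d. uniform over {0, 1, 2}.  The phenotype ramps up
over the first individuals, plateaus, and ramps up again at the end, so the
forced triangle rows are exactly the individuals with extreme phenotypes.

The triangle heights (defaults 20, 30, 40 for the left, middle and right
blocks) set the number of forced rows at each block's tip column and hence
the magnitude of the simulated gene signal; repeated scans averaged over
replicates show three peaks whose heights track the triangle heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .categorize import PhenotypeVector
from .scan import METHODS, GenotypeMatrix, scan

__all__ = [
    "TriangleSimConfig",
    "SimProfile",
    "make_genotype_matrix",
    "make_phenotype",
    "run_simulation",
    "write_profile_tsv",
]


@dataclass(frozen=True)
class TriangleSimConfig:
    """Parameters of the triangle simulation.

    Defaults reproduce the reference design: 500 individuals, 450 markers in
    three 150-wide blocks with triangle heights 20 / 30 / 40, averaged over
    100 replicates.
    """

    n_individuals: int = 500
    n_markers: int = 450
    block_width: int = 150
    heights: tuple = (20, 30, 40)
    n_reps: int = 100
    seed: int = 0
    methods: tuple = METHODS

    def __post_init__(self):
        object.__setattr__(self, "heights", tuple(self.heights))
        object.__setattr__(self, "methods", tuple(self.methods))
        if self.n_markers != len(self.heights) * self.block_width:
            raise ValueError(
                "n_markers must equal number of blocks x block_width"
            )
        if any(h > self.n_individuals / 2 for h in self.heights):
            raise ValueError("triangle height exceeds half the population")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def tip_columns(self) -> tuple:
        """1-based tip column of each block (block start + width/2)."""
        w = self.block_width
        return tuple(b * w + 1 + w // 2 for b in range(len(self.heights)))


@dataclass(frozen=True)
class SimProfile:
    """Mean per-marker score profile over replicates, one column per method
    (-log10 P for the two tests, raw coefficient for HA)."""

    scores: pd.DataFrame  # index: 1-based marker index; columns: methods
    n_reps: int
    config: TriangleSimConfig = field(repr=False)


def _triangle_depths(config: TriangleSimConfig) -> np.ndarray:
    """Forced depth per marker column (length n_markers).

    depth(j) = round(h * (1 - |j - c| / (w/2))) for the block containing
    column j, with tip column c; zero at and beyond the block edges.
    """
    w = config.block_width
    half = w / 2.0
    depths = np.zeros(config.n_markers, dtype=int)
    for b, h in enumerate(config.heights):
        c = config.tip_columns[b]
        for j in range(b * w + 1, (b + 1) * w + 1):
            frac = 1.0 - abs(j - c) / half
            if frac > 0:
                depths[j - 1] = int(round(h * frac))
    return depths


def make_genotype_matrix(config: TriangleSimConfig,
                         rng: np.random.Generator) -> GenotypeMatrix:
    """Draw one replicate genotype matrix.

    Background cells are i.i.d. uniform over {0, 1, 2}; then for each column
    with forced depth ``t``, the first ``t`` rows are set to 0 and the last
    ``t`` rows to 2 (the symmetric top/bottom triangles).
    """
    n, m = config.n_individuals, config.n_markers
    table = rng.integers(0, 3, size=(n, m))
    depths = _triangle_depths(config)
    for j, t in enumerate(depths):
        if t > 0:
            table[:t, j] = 0
            table[n - t:, j] = 2
    return GenotypeMatrix(
        ids=tuple(f"ind{i + 1}" for i in range(n)),
        markers=tuple(f"mk{j + 1}" for j in range(m)),
        labels=table.astype(object),
    )


def make_phenotype(config: TriangleSimConfig) -> PhenotypeVector:
    """Deterministic ramp / plateau / ramp phenotype.

    value(i) = i for i <= h_max; h_max on the plateau; then resumes rising by
    1 per individual over the last h_max individuals (defaults: 1..40, 40
    repeated, 41..80).  ``h_max`` is the tallest triangle height, so the
    ramps coincide with the tallest block's forced rows.
    """
    n = config.n_individuals
    h_max = max(config.heights)
    idx = np.arange(1, n + 1)
    values = np.where(
        idx <= h_max, idx,
        np.where(idx <= n - h_max, h_max, h_max + (idx - (n - h_max))),
    ).astype(float)
    return PhenotypeVector(ids=[f"ind{i}" for i in idx], values=values)


def run_simulation(config: TriangleSimConfig) -> SimProfile:
    """Repeat (draw matrix, scan, score) ``n_reps`` times and average.

    The master seed spawns one child seed per replicate, so any replicate is
    independently re-creatable; the phenotype is fixed across replicates.
    Scores are averaged after the -log10 transform for the two P-value
    methods and on the raw scale for HA.
    """
    pheno = make_phenotype(config)
    children = np.random.SeedSequence(config.seed).spawn(config.n_reps)
    score_col = {"hhccdf": "hh_ccdf_neglog10", "ftest": "f_neglog10", "ha": "ha"}
    acc = {m: np.zeros(config.n_markers) for m in config.methods}
    for child in children:
        geno = make_genotype_matrix(config, np.random.default_rng(child))
        res = scan(geno, pheno, methods=config.methods)
        for m in config.methods:
            acc[m] += res[score_col[m]].to_numpy(dtype=float)
    scores = pd.DataFrame(
        {m: acc[m] / config.n_reps for m in config.methods},
        index=pd.RangeIndex(1, config.n_markers + 1, name="marker_index"),
    )
    return SimProfile(scores=scores, n_reps=config.n_reps, config=config)


def write_profile_tsv(profile: SimProfile, path) -> None:
    """Write the mean score profile as TSV with a config-echo header."""
    cfg = profile.config
    with open(path, "w") as fh:
        fh.write(f"# hhccdf {__version__} simulation profile\n")
        fh.write(
            f"# individuals: {cfg.n_individuals}; markers: {cfg.n_markers}; "
            f"block_width: {cfg.block_width}; "
            f"heights: {','.join(map(str, cfg.heights))}; "
            f"reps: {cfg.n_reps}; seed: {cfg.seed}\n"
        )
        profile.scores.reset_index().to_csv(
            fh, sep="\t", index=False, float_format="%.6g"
        )
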