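"""Exception hierarchy for hhccdf.

All errors raised by the library derive from :class:`HhccdfError`, so callers
(and the CLI) can catch one type and still distinguish failure modes.
"""


class HhccdfError(Exception):
    """Base class for all hhccdf errors."""


class FormatError(HhccdfError):
    """A delimited input file could not be parsed (ragged rows, non-numeric
    phenotype, empty file)."""


class DuplicateId(FormatError):
    """An individual or marker identifier occurs more than once."""


class EmptyJoin(HhccdfError):
    """Genotype and phenotype tables share no individual identifiers."""


class DegenerateMarker(HhccdfError):
    """A marker has fewer than two genotype categories after missing-data
    removal; no boundary exists, so no statistic is defined."""


class InvalidCounts(HhccdfError):
    """Hypergeometric parameters violate 0 <= k <= d <= N, 0 <= K <= N."""


class NonPositiveInput(HhccdfError):
    """The HA coefficient needs positive phenotype mass: a negative trait
    value, or a boundary subset sum <= 0, was encountered."""


class DegenerateSpread(HhccdfError):
    """An operation that needs spread (min-max normalization, F test, HA
    denominator) received constant input."""
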