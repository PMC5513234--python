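"""Exception hierarchy.

All package-specific failures derive from :class:`BarcodevarError` so callers
can catch everything with one clause while tests can assert the precise kind.
"""


class BarcodevarError(Exception):
    """Base class for all barcodevar errors."""


class FormatError(BarcodevarError):
    """Malformed or empty input file."""


class AlignmentError(BarcodevarError):
    """Sequences violate alignment invariants (ragged lengths, bad alphabet)."""


class AlphabetError(AlignmentError):
    """Character outside the allowed nucleotide alphabet."""


class RegionBoundsError(BarcodevarError):
    """Region coordinates fall outside the alignment."""


class AnnotationError(BarcodevarError):
    """Gene table inconsistent with the alignment (overlap, frame, length)."""


class ReferenceMappingError(BarcodevarError):
    """A table refers to a sequence name that does not exist, or misses one."""


class UndefinedDistanceError(BarcodevarError):
    """A sequence pair has zero comparable sites; p-distance is undefined."""


class InsufficientDataError(BarcodevarError):
    """Too few sequences / sites / records for the requested statistic."""


class ParameterError(BarcodevarError):
    """Out-of-range or inconsistent user parameter."""


class DegenerateInputError(BarcodevarError):
    """Input is structurally valid but statistically degenerate (e.g. a
    zero-variance indicator vector from an all-N sequence)."""


class MatrixError(BarcodevarError):
    """Distance matrix is not symmetric / non-negative / zero-diagonal."""


class GenerationError(BarcodevarError):
    """Synthetic-sequence generation could not satisfy its constraints."""


class PipelineError(BarcodevarError):
    """A pipeline stage failed; message names the stage and the cause."""
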