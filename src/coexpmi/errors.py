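"""Exception hierarchy.

Every contract violation raises a distinct, named subclass of
:class:`CoexpmiError` so callers (and the CLI) can distinguish data errors
from usage errors.
"""


class CoexpmiError(Exception):
    """Base class for all errors raised by this package."""


class MatrixParseError(CoexpmiError):
    """The input file could not be parsed as an expression matrix."""


class DuplicateIdError(CoexpmiError):
    """Duplicate probe or sample identifiers."""


class EmptyMatrixError(CoexpmiError):
    """A matrix with zero probes or zero samples."""


class InvalidValueError(CoexpmiError):
    """Non-numeric, missing, non-finite or negative expression values."""


class LengthMismatchError(CoexpmiError):
    """Paired vectors (or schemes) built over different sample sets."""


class ZeroVarianceError(CoexpmiError):
    """Pearson correlation requested for a constant vector."""


class InvalidBinningError(CoexpmiError):
    """Bin count or range arguments violate the binning preconditions."""


class OutOfRangeError(CoexpmiError):
    """A value falls outside the declared range of a binning or histogram."""


class InsufficientSamplesError(CoexpmiError):
    """Fewer samples than bins requested for equal-frequency binning."""


class DegenerateInputError(CoexpmiError):
    """Too few distinct values (or too many ties) for the requested bins."""


class UnknownProbeError(CoexpmiError):
    """A probe identifier not present in the matrix."""


class SelfPairError(CoexpmiError):
    """A probe paired with itself; the candidate set excludes the query."""


class IndexMismatchError(CoexpmiError):
    """A rank index was built from a different matrix (fingerprint check)."""


class UndefinedScoreError(CoexpmiError):
    """Hybrid-score normalisation maxima are nonpositive."""
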