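"""Exception hierarchy shared across the package.

All errors raised by dynfc derive from :class:`DynfcError` so callers can
catch package failures with a single except clause while still seeing the
specific failure mode in the subclass.
"""


class DynfcError(Exception):
    """Base class for all dynfc errors."""


class ValidationError(DynfcError, ValueError):
    """Invalid argument or configuration value."""


class ParseError(DynfcError, ValueError):
    """A cell of a delimited input file failed numeric parsing."""


class StructuralError(DynfcError, ValueError):
    """Structurally malformed input (e.g. ragged rows in a matrix file)."""


class DegenerateInputError(DynfcError, ValueError):
    """Input is degenerate for the requested computation (e.g. a constant
    series handed to a correlation metric, or a rank-deficient regressor
    matrix for partial correlation)."""


class ConvergenceError(DynfcError, RuntimeError):
    """An iterative solver failed to converge within its iteration cap."""


class InsufficientWindowsError(DynfcError, ValueError):
    """Fewer than two window positions: the variance statistic is undefined."""
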