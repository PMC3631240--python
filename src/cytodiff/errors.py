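"""Exception hierarchy shared across the package.

All scientific-input violations derive from :class:`DomainError` (a
``ValueError``) so callers can distinguish "your numbers make no physical
sense" from programming errors.
"""


class CytodiffError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CytodiffError, ValueError):
    """An input lies outside the physically meaningful domain."""


class InsufficientDataError(DomainError):
    """Too few observations to perform the requested estimation."""


class DegenerateDesignError(DomainError):
    """The observations carry no information about the parameters
    (e.g. all dose ratios identical)."""


class DegenerateInputError(DomainError):
    """An input is structurally degenerate (constant image, single-bin
    histogram, rank-zero pixel matrix, ...)."""


class UndefinedIndexError(DomainError):
    """The apoptotic index is undefined (no tissue pixels)."""


class FormatError(CytodiffError, ValueError):
    """An input file or array does not have the expected layout."""


class PlacementError(CytodiffError, RuntimeError):
    """The synthetic-histology generator could not place the requested
    geometry without overlap."""
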