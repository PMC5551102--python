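"""Exception hierarchy.

Every error raised on a user-facing code path derives from
:class:`PrecocityError`, so callers can catch one type at pipeline level.
"""


class PrecocityError(Exception):
    """Base class for all package errors."""


class SchemaError(PrecocityError):
    """A table is missing required columns or is otherwise unreadable."""


class ValidationError(PrecocityError):
    """A table row or value violates an invariant (bad enum, non-positive size)."""


class InsufficientDataError(PrecocityError):
    """Too few observations to carry out an estimate."""


class DegenerateResponseError(PrecocityError):
    """All individuals flowered (or none did); the logistic fit is undefined."""


class DomainError(PrecocityError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class SpeciesLookupError(PrecocityError, KeyError):
    """A requested species is absent from a table."""


class TaxonomyLookupError(PrecocityError, KeyError):
    """A family in the trait table has no tip on the backbone tree."""


class CalibrationConflictError(PrecocityError):
    """Node ages are inconsistent (a child at least as old as its parent)."""


class DesignMatrixError(PrecocityError):
    """The regression design matrix is rank deficient."""


class NumericError(PrecocityError):
    """An optimizer or linear-algebra routine failed."""
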