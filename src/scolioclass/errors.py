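"""Exception hierarchy.

All package errors derive from :class:`ScolioClassError` so callers can catch
one type; subclasses distinguish malformed files, contract violations and
degenerate geometry, which the CLI maps onto distinct exit codes.
"""


class ScolioClassError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ScolioClassError):
    """A file does not follow the documented dialect (header, columns, grammar)."""


class ValidationError(ScolioClassError):
    """Well-formed input that violates a domain invariant (ordering, duplicates, NaN)."""


class DegenerateGeometryError(ScolioClassError):
    """Geometry on which the operation is undefined (coincident landmarks, zero chord)."""


class DegenerateTableError(ScolioClassError):
    """A contingency table with a zero row or column total (expected count 0)."""


class ContractError(ScolioClassError):
    """An operation called outside its precondition (e.g. empty region, id mismatch)."""
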