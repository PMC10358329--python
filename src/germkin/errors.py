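"""Exception hierarchy for germkin.

All package-specific failures derive from :class:`GermkinError` so callers
can catch one base class at the CLI boundary.
"""

from __future__ import annotations


class GermkinError(Exception):
    """Base class for all germkin errors."""


class FormatError(GermkinError):
    """The input table does not follow the paired wide-column layout."""


class ParseError(GermkinError):
    """A cell could not be parsed; carries 1-based row/column coordinates."""

    def __init__(self, message: str, row: int | None = None, column: int | None = None):
        self.row = row
        self.column = column
        if row is not None and column is not None:
            message = f"{message} (row {row}, column {column})"
        super().__init__(message)


class ValidationError(GermkinError):
    """A time course violates an invariant (non-monotone values, duplicate times)."""


class UndefinedIndexError(GermkinError):
    """A kinetics index is undefined for this course (e.g. level never reached).

    ``attained`` carries the maximum cumulative value actually observed, when
    relevant.
    """

    def __init__(self, message: str, attained: float | None = None):
        self.attained = attained
        super().__init__(message)


class FitError(GermkinError):
    """Nonlinear or linearized fitting failed in a non-recoverable way."""
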