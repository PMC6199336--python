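"""Exception hierarchy for forcematch.

All errors derive from :class:`ForceMatchError` so callers can catch the
package's failures with a single ``except`` clause; most also derive from
``ValueError`` because they signal invalid inputs rather than internal bugs.
"""

from __future__ import annotations


class ForceMatchError(Exception):
    """Base class for all forcematch errors."""


class InvalidArgumentError(ForceMatchError, ValueError):
    """An argument violates a documented precondition."""


class TraceTooShortError(ForceMatchError, ValueError):
    """The matching period does not contain one full analysis window."""


class DegenerateInputError(ForceMatchError, ValueError):
    """A statistic is undefined for this input (zero variance, all-tied, ...)."""


class EmptyInputError(DegenerateInputError):
    """No valid observations were supplied."""


class DegenerateDesignError(DegenerateInputError):
    """A regression design is uninformative (e.g. a single target level)."""


class CollinearityError(DegenerateInputError):
    """Exactly collinear predictors in a regression design.

    Attributes
    ----------
    columns : tuple of str
        Names of the offending predictor columns.
    """

    def __init__(self, message: str, columns: tuple[str, ...] = ()):
        super().__init__(message)
        self.columns = tuple(columns)


class ClinicalParseError(ForceMatchError, ValueError):
    """A clinical table failed validation.

    Attributes
    ----------
    problems : list of str
        One human-readable message per malformed cell, naming row and column.
    """

    def __init__(self, message: str, problems: list[str] | None = None):
        super().__init__(message)
        self.problems = list(problems or [])


class SubjectMismatchError(ForceMatchError, ValueError):
    """Subject identifiers do not reconcile across input tables.

    Attributes
    ----------
    orphans : tuple of str
        Subject ids present in one input but missing from the other.
    """

    def __init__(self, message: str, orphans: tuple[str, ...] = ()):
        super().__init__(message)
        self.orphans = tuple(orphans)
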