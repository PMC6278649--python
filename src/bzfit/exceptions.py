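"""Exception hierarchy for bzfit."""

from __future__ import annotations


class BzfitError(Exception):
    """Base class for all bzfit-specific errors."""


class DegenerateModelError(BzfitError, ValueError):
    """The model parameters describe a degenerate mechanism.

    Raised e.g. when K_BZ1 == 0: the cubic coefficients divide by K_BZ1,
    so the four-state mechanism collapses and cannot be solved as posed.
    """


class RootSelectionError(BzfitError, RuntimeError):
    """No unique physical root of the species cubic could be selected.

    Carries all candidate trigonometric roots so callers can diagnose
    (or fall back to the bracketing solver).
    """

    def __init__(self, message: str, candidates=()):
        super().__init__(message)
        self.candidates = tuple(candidates)


class NumericalDomainError(BzfitError, RuntimeError):
    """An intermediate quantity left its analytic domain beyond tolerance.

    For the closed-form cubic this instructs the caller to use the numeric
    bracketing solver instead.
    """


class UndefinedObservableError(BzfitError, ValueError):
    """The requested observable is undefined for this state.

    E.g. a protein-observed chemical shift with zero total protein.
    """


class DatasetValidationError(BzfitError, ValueError):
    """A titration dataset or CSV file violates its schema."""
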