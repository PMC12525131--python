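"""Exception hierarchy.

All package errors derive from :class:`PilotleError` so callers can catch
one base class at pipeline boundaries.
"""


class PilotleError(Exception):
    """Base class for all pilotle errors."""


class InvalidParameterError(PilotleError, ValueError):
    """A model or detector parameter violates its constraints."""


class InputError(PilotleError, ValueError):
    """An operation received structurally invalid input."""


class FormatError(InputError):
    """A file could not be parsed; the message locates the offending row."""


class InsufficientDataError(InputError):
    """Too few samples/bins to perform a fit."""


class FitFailureError(PilotleError, RuntimeError):
    """Nonlinear fit failed to converge from every starting point."""


class DegenerateBaselineError(PilotleError, ValueError):
    """EEG baseline epoch has zero amplitude spread (e.g. a flat trace)."""


class NoSeizuresError(PilotleError, ValueError):
    """A diary statistic requiring a first seizure was asked of a
    seizure-free diary; check ``epilepsy_status`` first."""
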