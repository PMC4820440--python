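"""Exception hierarchy shared across the package."""


class TimerRiderError(Exception):
    """Base class for all package errors."""


class DomainError(TimerRiderError):
    """An argument lies outside the mathematical domain of an operation.

    Deliberately not a ValueError subclass so that domain errors raised in
    model validators propagate as themselves instead of being absorbed
    into a generic validation error.
    """


class InvalidUnitError(DomainError):
    """A decision unit violates its invariants (non-positive threshold
    interval or rate SD)."""


class UndefinedQuantileError(DomainError):
    """The requested latency quantile falls in the defective mass of the
    distribution (non-positive promptness) and has no finite value."""


class InsufficientDataError(TimerRiderError):
    """Too few usable (non-censored) trials for the requested fit."""


class FitError(TimerRiderError):
    """A model fit failed or is degenerate beyond repair."""


class ConfigError(TimerRiderError):
    """A configuration document violates the schema or an invariant."""


class ParseError(TimerRiderError):
    """A trial-data file could not be parsed; the message names the row."""
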