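"""Exception hierarchy shared across the package."""


class ThermorevError(Exception):
    """Base class for all package errors."""


class ValidationError(ThermorevError, ValueError):
    """Raised when an input table, record or configuration violates its contract."""


class UndefinedStatisticError(ThermorevError, ArithmeticError):
    """Raised when a statistic is undefined for the given input.

    The reversal-rate and relative-survival formulas divide by (1 - control
    proportion); a control batch that is already 100% male (or with full
    survival) leaves nothing to reverse and the statistic has no value.
    """
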