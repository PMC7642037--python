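"""Exception hierarchy for the gelnet toolkit."""


class GelnetError(Exception):
    """Base class for all toolkit errors."""


class FormatError(GelnetError, ValueError):
    """An input file violates its format contract (bad cell, duplicate id, ...)."""


class ValidationError(GelnetError, ValueError):
    """An in-memory structure violates an invariant or precondition."""


class UndefinedStatisticError(GelnetError, ArithmeticError):
    """A statistic is mathematically undefined for the given input
    (e.g. correlation of a constant vector)."""
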