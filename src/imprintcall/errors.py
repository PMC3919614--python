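"""Exception hierarchy for the pipeline."""


class ImprintcallError(Exception):
    """Base class for all package errors."""


class ParseError(ImprintcallError, ValueError):
    """A file could not be parsed; message names the offending line."""


class ValidationError(ImprintcallError, ValueError):
    """An invariant on input data or configuration is violated."""


class UndefinedStatisticError(ImprintcallError, ZeroDivisionError):
    """A ratio or test is undefined for the given input (e.g. zero coverage)."""
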