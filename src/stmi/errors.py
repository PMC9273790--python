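"""Exception hierarchy shared across the pipeline stages."""


class STMIError(Exception):
    """Base class for all package errors."""


class ParameterError(STMIError, ValueError):
    """A configuration or function parameter is outside its valid domain."""


class DataError(STMIError, ValueError):
    """Input data violates a structural precondition (shape, labels, finiteness)."""


class NumericalError(STMIError, RuntimeError):
    """A numerical routine failed to produce a trustworthy result."""


class UndefinedMetricError(STMIError, ZeroDivisionError):
    """A performance metric has a zero denominator and is undefined."""
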