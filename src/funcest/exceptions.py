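"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class DegenerateTraceError(InvalidArgumentError):
    """A drawn trace has too few usable points to process."""


class DegenerateLabelsError(InvalidArgumentError):
    """A label table is empty or single-class after preparation."""


class UndefinedCorrelationError(InvalidArgumentError):
    """A correlation is requested on a zero-variance column."""


class NumericalError(ArithmeticError):
    """A matrix factorization failed even after jitter escalation."""
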