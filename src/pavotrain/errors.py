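"""Exception hierarchy shared by all pavotrain modules."""


class PavotrainError(Exception):
    """Base class for all pavotrain-specific errors."""


class InvalidParameterError(PavotrainError, ValueError):
    """A parameter violates its contract (wrong sign, range, or enum value)."""


class EmptyInputError(PavotrainError, ValueError):
    """An operation that requires a non-empty input received an empty one."""


class InsufficientPointsError(PavotrainError, ValueError):
    """A point-set statistic was asked for fewer points than it is defined on."""
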