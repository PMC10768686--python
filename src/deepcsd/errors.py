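"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class ConditioningError(RuntimeError):
    """A linear system is too ill-conditioned to solve reliably."""


class CoverageError(RuntimeError):
    """No gradient-direction subset passed the spherical-coverage check."""


class UndefinedACCError(ValueError):
    """ACC is 0/0: an argument has no energy above order zero."""
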