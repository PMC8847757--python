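"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A model parameter violates its documented domain."""


class InvalidScheduleError(ValueError):
    """An environment schedule would produce non-positive resources."""


class EmptyGroupError(ValueError):
    """A per-capita quantity was requested for a group with no members."""


class ShapeMismatchError(ValueError):
    """Replicate series passed to an aggregator have unequal lengths."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero-mean series)."""


class ScriptExhaustedError(RuntimeError):
    """A scripted RNG ran out of queued draws."""
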