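"""Exception hierarchy shared across the package."""


class KflbpcmError(Exception):
    """Base class for all package errors."""


class InvalidInputError(KflbpcmError, ValueError):
    """An array/image/label argument violates a precondition."""


class ConfigError(KflbpcmError, ValueError):
    """A configuration value violates its declared invariant."""


class DataError(KflbpcmError, ValueError):
    """A dataset on disk is missing, unreadable, or inconsistent."""


class StateError(KflbpcmError, RuntimeError):
    """An operation was applied in the wrong object state."""
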