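"""Structured exceptions used across the package."""


class SepsisNetError(Exception):
    """Base class for all package errors."""


class ParameterError(SepsisNetError, ValueError):
    """Invalid model parameter or configuration value.

    Carries the name of the offending field in ``field``.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DimensionError(SepsisNetError, ValueError):
    """State/parameter dimension mismatch; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class IntegrationError(SepsisNetError, RuntimeError):
    """ODE integration failure. ``last_good_time`` is the last time reached."""

    def __init__(self, message: str, last_good_time: float | None = None):
        self.last_good_time = last_good_time
        if last_good_time is not None:
            message = f"{message} (last good time: {last_good_time})"
        super().__init__(message)


class NoSynchronizedStateError(SepsisNetError, ValueError):
    """The interlayer coupling is below the existence bound for the
    fully synchronized duplex state."""
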