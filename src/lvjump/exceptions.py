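"""Exception hierarchy for lvjump."""


class LVJumpError(Exception):
    """Base class for all lvjump errors."""


class InvalidParameterError(LVJumpError, ValueError):
    """A model or noise parameter violates its constraints."""


class ConfigurationError(LVJumpError, ValueError):
    """A run configuration is malformed or inconsistent."""


class NumericalError(LVJumpError, RuntimeError):
    """A numerical routine failed to reach its accuracy or closure target."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ModelRegimeError(LVJumpError, RuntimeError):
    """The parameter regime admits no normalizable stationary density."""


class GridExtensionNeeded(LVJumpError, RuntimeError):
    """The level grid does not reach far enough into the tail of p0.

    Carries the suggested new upper level so callers can rebuild the
    orbit table and retry.
    """

    def __init__(self, message: str, suggested_r_max: float):
        super().__init__(message)
        self.suggested_r_max = suggested_r_max


class AccuracyError(LVJumpError, RuntimeError):
    """A computed quantity failed a built-in accuracy check (e.g. PDF mass)."""
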