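"""Exception hierarchy for bonerheo."""


class BoneRheoError(Exception):
    """Base class for all bonerheo errors."""


class ParameterError(BoneRheoError, ValueError):
    """Invalid material parameters or parameter ranges."""


class SignalError(BoneRheoError, ValueError):
    """Invalid excitation signal (non-monotone time, NaN, length mismatch...)."""


class IntegrationError(BoneRheoError, RuntimeError):
    """Time integration failed (e.g. non-convergent return-mapping root find)."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class ConfigError(BoneRheoError, ValueError):
    """Invalid protocol / cohort / optimizer configuration."""


class SpecimenParseError(BoneRheoError, ValueError):
    """Malformed specimen file."""
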