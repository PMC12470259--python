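"""Exception hierarchy shared across the package."""


class HippsegError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HippsegError):
    """An invalid or inconsistent configuration value."""


class ValidationError(HippsegError):
    """Invalid input data (shapes, dtypes, value ranges)."""


class ShapeError(ValidationError):
    """Tensor/array shape mismatch; message names both shapes."""


class DegenerateTestError(HippsegError):
    """A statistical test whose assumptions collapse (e.g. zero-variance
    paired differences with a nonzero mean)."""
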