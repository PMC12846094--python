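"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class FilterDesignError(ValidationError):
    """A filter specification cannot be realised at the given sampling rate."""


class UndefinedFeatureError(ValidationError):
    """A feature is mathematically undefined for the given input (e.g. zero-power spectrum)."""


class LeakageError(RuntimeError):
    """Subject-level data leakage detected in a cross-validation fold. Always fatal."""


class UnavailableBackboneError(RuntimeError):
    """A named convolutional backbone is not available in this environment."""
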