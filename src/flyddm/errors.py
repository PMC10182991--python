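"""Exception types shared across the package."""


class FlyddmError(Exception):
    """Base class for package-specific errors."""


class SchemaError(FlyddmError):
    """A required column or field is missing from an input table."""


class ValidationError(FlyddmError):
    """A value violates a domain invariant (e.g. a non-positive reaction time)."""


class UnderdeterminedError(FlyddmError):
    """Fewer data cells than free parameters; the fit has no unique solution."""


class DegenerateModelError(FlyddmError):
    """Model parameters give a numerically degenerate process.

    Raised e.g. when both single-interval crossing probabilities of the
    extrema-detection process underflow to zero, which makes the expected
    decision time infinite.  The fix is a larger sampling interval or a
    smaller bound height.
    """


class ConfigError(FlyddmError):
    """Invalid run configuration (CLI / YAML level)."""
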