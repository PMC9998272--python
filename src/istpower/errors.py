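"""Exception types raised across the package."""


class InvalidParameterError(ValueError):
    """A user-supplied parameter is outside its valid domain."""


class DegenerateTypeError(ValueError):
    """A cell type has zero assigned mass, leaving a quantity undefined."""


class OptimizationFailureError(RuntimeError):
    """The assignment optimizer diverged (non-finite loss)."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class UnfittableError(ValueError):
    """The data cannot support the requested model fit."""


class EstimationError(RuntimeError):
    """Parameter estimation failed; carries diagnostic context."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnattainableError(ValueError):
    """The requested target cannot be reached under the given inputs."""


class DegenerateComparisonError(ValueError):
    """A statistical comparison is undefined (e.g. zero variance)."""


class SchemaError(ValueError):
    """An input table does not conform to the expected schema."""
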