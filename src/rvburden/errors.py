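"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class SchemaError(ValueError):
    """An input table does not conform to the documented column schema."""


class DataConsistencyError(ValueError):
    """Cross-references between tables (variant keys, sample ids) do not resolve."""


class AnnotationError(ValueError):
    """A variant record lacks the information required for an operation."""


class DegeneratePredictorError(ValueError):
    """A burden genotype has no variation, so no association model can be fit."""


class EstimationError(RuntimeError):
    """A model fit failed (rank deficiency, empty input, non-convergence)."""
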