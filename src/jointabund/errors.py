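"""Exception types shared across the pipeline stages."""


class JointAbundError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(JointAbundError):
    """Survey design parameters are inconsistent or nonpositive."""


class UnknownCovariateError(JointAbundError):
    """A requested model term references a covariate absent from the data."""


class DegenerateSurveyError(JointAbundError):
    """A survey type has zero response variance and cannot be standardized."""


class EmptyDatasetError(JointAbundError):
    """Complete-case restriction left no analysis rows."""


class SingularDesignError(JointAbundError):
    """The fixed-effect design matrix is rank deficient."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(f"rank-deficient fixed design; aliased terms: {self.aliased}")


class SampleTooSmallError(JointAbundError):
    """AICc small-sample correction undefined (n - k - 1 <= 0)."""


class MissingTermError(JointAbundError):
    """An effect summary was requested for a term the fitted model lacks."""


class PipelineError(JointAbundError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, cause):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
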