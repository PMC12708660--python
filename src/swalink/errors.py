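"""Exception hierarchy shared across the pipeline."""


class SwalinkError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SwalinkError, ValueError):
    """A configuration value is inconsistent or out of its valid range."""


class ScoringError(SwalinkError, ValueError):
    """Too few usable trials (or another task-structure problem) to score."""


class DegenerateInputError(SwalinkError, ValueError):
    """An input with zero variance where a spread statistic is required."""


class AlignmentError(SwalinkError, ValueError):
    """Two inputs that must share a grid/length/montage do not."""


class EmptySelectionError(SwalinkError, ValueError):
    """A stage/artifact selection left no usable epochs."""


class NormalizationError(SwalinkError, ValueError):
    """A map cannot be normalized (all-zero total current density)."""


class InputIntegrityError(SwalinkError, ValueError):
    """A matrix that must be (near) positive semidefinite is not."""


class NumericalConditioningError(SwalinkError, ArithmeticError):
    """A linear-algebra step failed beyond pseudo-inverse tolerance."""


class BundleValidationError(SwalinkError, ValueError):
    """One or more subject files in a study bundle failed validation."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class PipelineError(SwalinkError, RuntimeError):
    """The end-to-end pipeline cannot proceed (e.g. too few subjects)."""
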