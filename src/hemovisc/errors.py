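"""Exception hierarchy for hemovisc."""


class HemoviscError(Exception):
    """Base class for all hemovisc errors."""


class DomainError(HemoviscError, ValueError):
    """An input value is outside the physical/physiological domain."""


class ImplausibleInputError(DomainError):
    """Inputs individually valid but jointly produce a nonphysical result."""


class SubjectValidationError(DomainError):
    """A subject record violates an invariant; carries the subject id."""

    def __init__(self, subject_id: str, message: str):
        self.subject_id = subject_id
        super().__init__(f"subject {subject_id!r}: {message}")


class UnsupportedClassError(HemoviscError):
    """Operation requested for a BMI class with no calibrated model (thin)."""


class FitError(HemoviscError):
    """Regression calibration failed."""


class RankDeficiencyError(FitError):
    """Design matrix is rank deficient (collinear regressors)."""


class InsufficientDataError(FitError):
    """Too few rows to fit the model."""


class GenerationError(HemoviscError):
    """Synthetic cohort generation could not satisfy its constraints."""


class SchemaError(HemoviscError):
    """Input file does not match the expected tabular schema."""


class ConfigError(HemoviscError):
    """Invalid pipeline or generator configuration."""
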