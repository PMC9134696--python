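"""Exception hierarchy shared across the pipeline stages."""


class CheSurveyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CheSurveyError):
    """Invalid generator or pipeline configuration; names the offending field."""


class ValidationError(CheSurveyError):
    """Invalid survey data (negative money, malformed member rows, ...)."""


class DegenerateHouseholdError(CheSurveyError):
    """A household that should have been excluded upstream (e.g. zero consumption)."""


class BandError(CheSurveyError):
    """The food-share percentile band selects no households, even after fallback."""


class SeparationError(CheSurveyError):
    """Perfect or quasi-perfect separation detected during logistic fitting."""


class RankDeficiencyError(CheSurveyError):
    """Design matrix is rank deficient; carries the suspect column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class HosmerLemeshowError(CheSurveyError):
    """A decile group has zero expected events or non-events."""
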