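"""Exception hierarchy for cohort validation and analysis configuration."""


class MbrCeaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MbrCeaError):
    """A required column is missing from an input table."""


class CohortValidationError(MbrCeaError):
    """A value violates the domain constraints (enum membership, range)."""


class ReferentialError(MbrCeaError):
    """A cost row references a participant id not present in the cohort."""


class ConfigError(MbrCeaError):
    """An analysis or simulation configuration value is invalid."""


class DataCompletenessError(MbrCeaError):
    """A participant lacks the quarterly coverage an operation requires."""


class SeparationError(MbrCeaError):
    """A covariate perfectly separates the treatment arms."""


class RankDeficiencyError(MbrCeaError):
    """The propensity design matrix is rank deficient (collinear columns)."""


class EmptyAnalysisSetError(MbrCeaError):
    """A pipeline stage emptied one or both arms of the analysis set."""
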