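"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`SeqTrialError` so the CLI can map
failures to stable, machine-parsable exit codes.
"""


class SeqTrialError(Exception):
    """Base class for all pipeline errors."""

    #: short machine-parsable code emitted by the CLI on failure
    code = "E_PIPELINE"


class ValidationError(SeqTrialError):
    """Invalid value passed to a scoring or configuration function."""

    code = "E_VALIDATION"


class ConfigError(SeqTrialError):
    """Infeasible or inconsistent configuration."""

    code = "E_CONFIG"


class DataError(SeqTrialError):
    """Input data violate a structural contract (e.g. non-monotone vaccination)."""

    code = "E_DATA"


class EstimationError(SeqTrialError):
    """Model fitting failed (non-convergence, separation, empty stratum)."""

    code = "E_ESTIMATION"
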