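"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid generator or model configuration; message names the field."""


class CohortParseError(ValueError):
    """Malformed cohort file; message names the row and column."""


class EstimationError(RuntimeError):
    """A statistical fit failed (separation, non-convergence, degenerate labels)."""
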