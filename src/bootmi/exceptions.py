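"""Exception hierarchy.

Everything raised deliberately by the package derives from :class:`BootmiError`
so callers (and the CLI) can separate user-facing problems from genuine bugs.
"""


class BootmiError(Exception):
    """Base class for all errors raised by bootmi."""


class DataError(BootmiError, ValueError):
    """A dataset violates an invariant (non-numeric column, bad binary column, ...)."""


class SpecError(BootmiError, ValueError):
    """An imputation/analysis specification is internally inconsistent."""


class ImputationError(BootmiError):
    """The imputation model cannot be fitted or applied (singular design,
    missing predictor values, too few complete rows)."""


class EstimationError(BootmiError):
    """The analysis model cannot be fitted (collinearity, empty subgroup,
    exhausted bootstrap redraws)."""


class ConfigError(BootmiError, ValueError):
    """A configuration file is missing keys or contains invalid values."""
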