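"""Exception hierarchy shared across the pipeline stages.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems exit 3, numerical failures exit 4.
"""


class BnDissectError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BnDissectError):
    """Invalid generator/pipeline configuration (bad bounds, unknown keys...)."""


class DataError(BnDissectError):
    """Inconsistent or missing input data (unknown gene, shape mismatch...)."""


class NumericalError(BnDissectError):
    """A numerical procedure failed (degenerate mixture fit, singular system)."""


class UndefinedWeightError(NumericalError):
    """Both true-positive proportions are zero; the annotation weight w is undefined."""
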