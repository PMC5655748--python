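"""Exceptions shared across the package."""


class CausalTrioError(Exception):
    """Base class for package-specific errors."""


class DegenerateDataError(CausalTrioError, ValueError):
    """Raised when the data carry no usable signal for a fit.

    Examples: a zero-variance genotype or outcome vector, a singular
    sample covariance matrix, or a genotype level with too few
    observations to estimate a within-level variance.
    """


class InvalidScenarioError(CausalTrioError, ValueError):
    """Raised for an unknown scenario identifier."""
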