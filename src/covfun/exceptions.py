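"""Exception hierarchy for covfun.

All package-specific failures derive from :class:`CovFunError` so callers can
catch everything with one clause; the finer classes distinguish bad user
parameters from numerically degenerate data situations.
"""


class CovFunError(Exception):
    """Base class for all covfun errors."""


class InvalidParameterError(CovFunError, ValueError):
    """A parameter is outside its valid domain (e.g. nonpositive bandwidth)."""


class ExtrapolationError(CovFunError):
    """Total kernel weight at the requested point is effectively zero.

    Raised instead of returning NaN: kernel estimates outside the range of
    the observed covariates are unreliable and should not be produced
    silently.
    """


class DegenerateNeighborhoodError(CovFunError):
    """The local design matrix is rank-deficient at the requested point."""


class NoValidBandwidthError(CovFunError):
    """Every candidate bandwidth in a cross-validation grid was degenerate."""


class EmptyCellError(CovFunError):
    """No observations match the requested factor level under lambda = 1."""


class SingularMatrixError(CovFunError):
    """The combined covariance matrix is not positive definite."""


class LogitDomainError(CovFunError):
    """The leading eigenvalue is exactly 0 or 1; its logit is undefined."""


class DataError(CovFunError):
    """Input data violates a preprocessing contract (e.g. log of a zero)."""


class ConfigError(CovFunError):
    """An analysis configuration is inconsistent or incomplete."""
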