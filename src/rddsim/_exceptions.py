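"""Exception hierarchy shared across the package."""


class RDDSimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RDDSimError, ValueError):
    """A distribution or model parameter is outside its admissible range."""


class FeasibilityError(ParameterError):
    """A requested (mean, variance) pair is not representable by a
    beta-binomial distribution with the given maximum count."""


class DegenerateDistributionError(ParameterError):
    """The requested distribution collapses to a point mass; use
    :func:`rddsim.distributions.point_mass` instead of shape parameters."""


class ConfigurationError(RDDSimError, ValueError):
    """A scenario or model configuration is inconsistent or incomplete."""


class UndefinedStatisticError(RDDSimError, ValueError):
    """A statistic is undefined for the given input (e.g. a correlation
    with a zero-variance margin)."""
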