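"""Exception and warning types used across the package."""


class BidirMRError(Exception):
    """Base class for all package errors."""


class ParameterError(BidirMRError, ValueError):
    """An argument is outside its documented domain."""


class DataError(BidirMRError, ValueError):
    """Input data violate a structural requirement (alleles, signs, bounds)."""


class ConfigurationError(BidirMRError, ValueError):
    """A configuration file or mapping is inconsistent or incomplete."""


class DegenerateFitError(BidirMRError, ValueError):
    """A regression cannot be fitted meaningfully (zero variance, perfect fit,
    rank deficiency)."""


class WeakInstrumentError(BidirMRError, ValueError):
    """The first-stage association is too weak for IV estimation (F below the
    hard floor)."""


class WeakInstrumentWarning(UserWarning):
    """First-stage F below the advisory floor (default 10); estimates may be
    biased toward the observational slope."""
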