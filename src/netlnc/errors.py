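"""Exception hierarchy shared across the package."""


class NetLncError(Exception):
    """Base class for all package-specific errors."""


class IngestError(NetLncError):
    """A file failed validation on read (malformed line, bad value, duplicate id)."""


class ConfigurationError(NetLncError):
    """Inconsistent or unusable parameters / inputs (e.g. no seed gene present)."""


class InsufficientDataError(NetLncError):
    """Too few jointly observed values to compute the requested statistic."""


class DegenerateDataError(NetLncError):
    """A statistic is undefined for this input (zero variance, |r| = 1 covariate, ...)."""
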