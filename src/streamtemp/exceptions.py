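"""Exception types shared across the package."""


class StreamTempError(Exception):
    """Base class for streamtemp errors."""


class DataError(StreamTempError, ValueError):
    """Raised when input data violate a structural contract
    (duplicate timestamps, missing site covariates, rank-deficient design)."""


class ConvergenceError(StreamTempError, RuntimeError):
    """Raised when a downstream computation requires a converged fit."""


class AnalysisError(StreamTempError, RuntimeError):
    """Raised when a multi-model analysis (e.g. all-subsets enumeration)
    cannot be completed."""


class UndefinedMetricError(StreamTempError, ZeroDivisionError):
    """Raised when a variance-ratio metric is undefined (zero denominator)."""
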