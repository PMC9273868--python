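"""Exception hierarchy.

Three broad classes so callers (and the CLI exit codes) can distinguish
bad configuration, bad data, and computations that are undefined for the
given inputs.
"""


class TargetscoutError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TargetscoutError):
    """Invalid configuration (bad thresholds, empty weight sets, ...)."""


class DataError(TargetscoutError):
    """Malformed or insufficient input data."""


class InsufficientReplicationError(DataError):
    """Fewer than two samples in a comparison arm."""


class UndefinedStatisticError(TargetscoutError):
    """A statistic is undefined for the given counts (e.g. empty background)."""
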