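"""Exception hierarchy.

The CLI maps these onto distinct exit codes so callers can tell a bad
configuration apart from bad data or from a statistic that degenerated
(e.g. a zero standard error).
"""


class DualChangeError(Exception):
    """Base class for all package errors."""


class InputError(DualChangeError, ValueError):
    """A value passed to an operation violates its contract."""


class ConfigError(DualChangeError, ValueError):
    """A run/scale/simulation configuration is invalid."""


class DataError(DualChangeError):
    """Input data cannot be analysed as requested (shape, missingness, singularity)."""


class DegenerateStatisticsError(DualChangeError):
    """A statistic is undefined for this input (zero variance, zero SEdiff, all ties)."""
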