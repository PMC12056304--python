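"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and its
subclasses) -> 3. Everything derives from PlaquemetricsError so library users
can catch one type.
"""


class PlaquemetricsError(Exception):
    """Base class for all package errors."""


class ConfigError(PlaquemetricsError):
    """Invalid configuration (unknown keys, bad units, unresolvable paths)."""


class DataError(PlaquemetricsError):
    """Invalid or missing input data."""


class MeasurementError(DataError):
    """A measurement is undefined for the given input (empty mask, tiny ROI...)."""


class UsageError(PlaquemetricsError):
    """An operation was called with arguments outside its contract."""
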