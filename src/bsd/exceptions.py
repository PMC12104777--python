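"""Exception hierarchy.

CLI exit codes: configuration errors -> 2, data/format errors -> 3,
numerical failures -> 4.
"""


class BSDError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(BSDError):
    """Invalid or inconsistent configuration."""

    exit_code = 2


class ValidationError(ConfigError):
    """A domain object violates its invariants."""


class DimensionError(ValidationError):
    """Shapes or lengths of related objects do not match."""


class DataFormatError(BSDError):
    """Malformed input data (tables, spectra files)."""

    exit_code = 3


class NumericalError(BSDError):
    """Numerical failure (singular curvature, invalid reduction, ...)."""

    exit_code = 4
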