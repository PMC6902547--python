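"""Exception hierarchy.

Config-shaped problems (bad parameters, bad schemas) and data-shaped problems
(series too short, degenerate inputs) are kept on separate branches so the CLI
can map them to distinct exit codes.
"""


class StridestabError(Exception):
    """Base class for all package errors."""


class ConfigError(StridestabError):
    """Invalid configuration or parameterization."""


class SchemaError(ConfigError):
    """A file does not match the expected columnar schema."""


class ParameterError(ConfigError):
    """An operation was called with out-of-range parameters."""


class NonStationaryError(ParameterError):
    """A (phi1, phi2) pair violates the AR(2) stationarity inequalities."""


class DataError(StridestabError):
    """Invalid or unusable input data."""


class ShortSeriesError(DataError):
    """Series shorter than the minimum length required for fitting."""


class DegenerateSeriesError(DataError):
    """Cleaning removed every stride, or the series carries no information."""


class DegenerateFitError(DataError):
    """The AR regression design matrix is singular (e.g. constant residuals)."""


class DegenerateGeometryError(DataError):
    """Point cloud is collinear/degenerate; no coverage ellipse exists."""


class ClassBalanceError(DataError):
    """Classification requires two classes; input has fewer."""


class AggregationError(DataError):
    """Group-level aggregation over an empty group."""
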