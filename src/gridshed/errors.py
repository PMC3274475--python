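"""Exception hierarchy shared across the package."""


class GridshedError(Exception):
    """Base class for all package-specific failures."""


class ConvergenceError(GridshedError):
    """Iterative geodesic solution failed to converge (nearly antipodal points)."""


class SchemaError(GridshedError):
    """An input table violates its declared schema."""


class CalendarError(GridshedError):
    """Date coverage of an input is incomplete or inconsistent."""


class ConfigError(GridshedError):
    """A run or simulation configuration is invalid."""
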