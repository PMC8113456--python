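"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` subclasses to exit
code 3; everything else is a programming error and propagates.
"""


class FtirchemError(Exception):
    """Base class for all package errors."""


class ConfigError(FtirchemError):
    """Invalid configuration or parameter values."""


class DataError(FtirchemError):
    """Invalid or inconsistent data."""


class GridError(DataError):
    """Wavenumber grid violates monotonicity/uniform-spacing contracts."""


class FormatError(DataError):
    """Malformed input file."""


class RangeError(DataError):
    """Requested spectral range does not overlap the grid."""


class MetadataError(DataError):
    """Inconsistent per-spectrum or per-sample metadata."""


class NormalizationError(DataError):
    """A spectrum cannot be normalized (zero norm)."""


class DegenerateDataError(DataError):
    """Zero-variance or otherwise degenerate numerical input."""


class SearchError(FtirchemError):
    """A bracketed numerical search failed to terminate within bounds."""
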