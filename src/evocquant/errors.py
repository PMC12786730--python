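"""Exception hierarchy shared across the pipeline stages."""


class EvocQuantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EvocQuantError):
    """Raised for malformed input data (wrong shape, dtype, schema)."""


class ConfigurationError(EvocQuantError):
    """Raised for invalid parameters or configuration values."""


class ValidationError(EvocQuantError):
    """Raised when structured records violate their contracts."""


class EmptyRoiError(EvocQuantError):
    """Raised when a region of interest contains no polygons.

    Distinct from the legitimate outcome of zero nuclei falling inside a
    valid, non-empty ROI.
    """


class CapacityError(EvocQuantError):
    """Raised when a simulated tile cannot hold the requested nuclei."""


class DegenerateDataError(EvocQuantError):
    """Raised when input data have no variance where variance is required."""
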