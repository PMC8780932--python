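"""Exception hierarchy.

Every anticipated failure mode maps to a distinct subclass so callers (and
the CLI) can turn them into actionable messages instead of tracebacks.
"""


class HistoquantError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HistoquantError):
    """A parameter is outside its documented domain (levels, intervals, ...)."""


class AnnotationError(HistoquantError):
    """A region annotation is malformed or references a missing image."""


class EmptyRegionError(AnnotationError):
    """A polygon covers no pixel centers (degenerate or off-image annotation)."""


class TrainingError(HistoquantError):
    """Training input cannot produce a usable classifier.

    Raised when annotations lack a positive or a negative region — the
    resulting color table would be degenerate.
    """


class EmptyPaletteError(HistoquantError):
    """No quantized color passed the positive-fraction threshold for any class."""


class IncompatibleTablesError(HistoquantError):
    """Two color tables disagree on quantization levels or class declarations."""


class UndefinedDenominatorError(HistoquantError):
    """tissue_only percent area requested but the image has zero tissue pixels."""


class UndefinedRatioError(HistoquantError):
    """Class-area ratio with an empty denominator mask; reported as missing downstream."""


class InfeasibleSpecError(HistoquantError):
    """A synthetic-image spec cannot be realized (target area vs. geometry)."""


class ImageFormatError(HistoquantError):
    """An input raster is not a usable 8-bit RGB image (e.g. multi-page TIFF)."""
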