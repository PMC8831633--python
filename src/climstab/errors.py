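"""Exception hierarchy for the climstab pipeline."""


class ClimstabError(Exception):
    """Base class for all climstab errors."""


class GridAlignmentError(ClimstabError):
    """Raised when rasters that must share a grid do not."""


class GeoTiffError(ClimstabError):
    """Raised on unreadable, multi-band or non-georeferenced files."""


class ConstantLayerError(ClimstabError):
    """Raised when a Pearson correlation is undefined because one
    input is constant on the evaluated pixels."""


class InsufficientPixelsError(ClimstabError):
    """Raised when fewer valid pixels exist than an operation requires."""


class PreflightError(ClimstabError):
    """Raised before any computation when a referenced input is missing."""
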