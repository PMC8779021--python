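"""Exception types raised by the viability pipeline."""


class ViaquantError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(ViaquantError):
    """Image file format is not an accepted lossless raster (TIFF/PNG)."""


class UnsupportedDepthError(ViaquantError):
    """Image is not 8 bits per channel; no silent conversion is performed."""


class ManifestError(ViaquantError):
    """Sample manifest violates the dataset contract (columns, markers, group sizes)."""


class NormalizationError(ViaquantError):
    """A frame has no zero-brightness pixel, so dark-pixel normalization is undefined."""


class UndefinedRatioError(ViaquantError):
    """The red (non-viable) aggregate feature is zero: no detectable dead-cell signal."""


class ZeroVarianceError(ViaquantError):
    """A metrics column is constant and cannot be z-scored."""
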