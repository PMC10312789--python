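"""Exception hierarchy shared across the package."""


class XLFlowError(Exception):
    """Base class for all package errors."""


class GeometryError(XLFlowError):
    """Lens layout / image geometry is inconsistent."""


class ShapeError(XLFlowError):
    """Array shapes are incompatible with the requested operation."""


class DetectionError(XLFlowError):
    """Lens-center detection found fewer qualifying peaks than requested."""


class OperatorError(XLFlowError):
    """The linear imaging operator is degenerate (e.g. all-zero PSF)."""


class InputError(XLFlowError):
    """An input violates a precondition (e.g. negative intensities)."""


class ConfigError(XLFlowError):
    """Configuration values are inconsistent with the model architecture."""


class DataError(XLFlowError):
    """A dataset is empty or malformed."""
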