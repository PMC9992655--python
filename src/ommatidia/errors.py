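"""Typed errors raised by the detection and measurement pipelines."""


class OmmatidiaError(Exception):
    """Base class for all package errors."""


class NoSignalError(OmmatidiaError):
    """The image carries no periodic signal (e.g. constant intensity)."""


class LatticeNotFoundError(OmmatidiaError):
    """Fewer significant reciprocal-space peaks than fundamentals requested."""


class IllConditionedError(OmmatidiaError):
    """Geometric fit is degenerate (e.g. coplanar points for a sphere fit)."""


class EmptySelectionError(OmmatidiaError):
    """A density or mask filter selected no voxels/pixels."""


class ContrastError(OmmatidiaError):
    """Requested contrast manipulation is not a pure reduction."""


class UndefinedMeasureError(OmmatidiaError):
    """A measurement is undefined for the given input (e.g. < 2 centers)."""


class FormatError(OmmatidiaError):
    """An input file or stack does not match the declared format."""
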