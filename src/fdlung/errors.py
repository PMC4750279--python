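"""Exception hierarchy used across the package."""


class FdlungError(Exception):
    """Base class for all package errors."""


class VolumeFormatError(FdlungError):
    """A volume file could not be parsed, or its metadata is inconsistent."""


class ValidationError(FdlungError):
    """Input data violates a structural requirement (shapes, finiteness, emptiness)."""


class ParameterError(FdlungError, ValueError):
    """A parameter value is structurally invalid."""


class SegmentationError(FdlungError):
    """No lung-like region could be extracted from the volume."""


class FitError(FdlungError):
    """A curve fit failed or its preconditions are not met."""


class DegenerateFitError(FitError):
    """The data cannot support the requested curve fit at all."""


class InfeasibleTargetError(FdlungError):
    """A phantom target curve demands more occupancy than the mask can supply."""
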