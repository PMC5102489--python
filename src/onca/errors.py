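"""Exception hierarchy shared across the pipeline stages."""


class OncaError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(OncaError, ValueError):
    """An argument is outside its documented domain."""


class NoDataError(OncaError):
    """An operation received an empty or fully masked input."""


class InconsistentInputError(OncaError):
    """Inputs that must agree (schemas, station ids, raster grids) do not."""


class InfeasibleSampleError(OncaError):
    """A without-replacement sample was requested that exceeds the population."""


class UndefinedMMDMError(OncaError):
    """No individual was detected at two or more distinct camera stations,
    so the mean maximum distance moved (and hence density) is undefined."""


class DegenerateGeometryError(OncaError):
    """Fewer than three non-collinear stations: no convex polygon exists."""


class MissingTraitError(OncaError, KeyError):
    """A species is absent from the traits table."""


class NoSignalError(OncaError):
    """A waveform never rises above the noise threshold."""


class ModelStateError(OncaError, RuntimeError):
    """An operation requires a fitted model."""
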