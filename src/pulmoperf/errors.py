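"""Exception hierarchy.

Every error raised by the library derives from :class:`PulmoperfError`, split
into configuration/parameter problems (CLI exit code 2) and data/signal
problems (CLI exit code 3).
"""


class PulmoperfError(Exception):
    """Base class for all pulmoperf errors."""


class ParameterError(PulmoperfError, ValueError):
    """Invalid parameter or configuration value."""


class SpecificationError(ParameterError):
    """A phantom or run specification is internally inconsistent."""


class DataError(PulmoperfError, ValueError):
    """Input data violates a structural precondition (shape, emptiness)."""


class GeometryError(DataError):
    """A volume-of-interest does not intersect the image grid."""


class NoTriggerError(DataError):
    """Bolus tracking never reached the enhancement threshold."""


class BaseNotFoundError(DataError):
    """No frame satisfies the base-of-enhancement criterion."""


class SignalError(DataError):
    """An enhancement curve is unusable (e.g. non-positive peak)."""


class DegenerateInputError(DataError):
    """Input is degenerate for the requested computation (zero mass/variance)."""
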