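"""Exception hierarchy used across the package."""


class ImcsegError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ImcsegError, ValueError):
    """A parameter or config field violates its documented bounds."""


class InputError(ImcsegError, ValueError):
    """Runtime input (shapes, sizes, empty collections) is invalid."""


class BoundsError(ImcsegError, ValueError):
    """A coordinate or rectangle falls outside the image grid."""


class AnnotationError(ImcsegError, ValueError):
    """Boundary annotation is internally inconsistent (e.g. crossing interfaces)."""


class MeasurementError(ImcsegError, ValueError):
    """A measurement cannot be made (e.g. empty mask: no IMC detected)."""
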