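"""Exception hierarchy shared across the pipeline stages."""


class DrsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DrsError):
    """A user-supplied configuration value is invalid; the message names the field."""


class ValidationError(DrsError):
    """Input data violate a precondition (shape, labels, emptiness, ...)."""


class GeometryError(DrsError):
    """Requested synthetic geometry does not fit inside the image bounds."""


class DegenerateClusterError(ValidationError):
    """Within-cluster scatter is numerically zero; a Fisher ratio is undefined."""


class DataQualityError(DrsError):
    """Every candidate evaluated degenerate; the feature bank cannot drive a search."""


class StateError(DrsError):
    """An object was used before being fitted/initialized."""


class LeakageError(DrsError):
    """Biological source identifiers cross a train/evaluation boundary."""
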