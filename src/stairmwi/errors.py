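"""Exception hierarchy for the toolkit."""


class StairError(Exception):
    """Base class for all toolkit errors."""


class InvalidProtocolError(StairError):
    """A sequence-parameter set is inconsistent with the requested model."""


class DomainError(StairError, ValueError):
    """A numeric argument is outside the model's domain of validity."""


class GeometryError(StairError):
    """Volumes disagree in shape, voxel size or orientation."""


class ConfigError(StairError):
    """A configuration file or mode string could not be interpreted."""


class IntegratorError(StairError):
    """The Bloch integrator produced a non-physical trajectory."""


class PlacementError(StairError):
    """Phantom lesions could not be placed without overlap."""


class DegenerateDataError(StairError):
    """A statistical routine received data with no usable variance."""
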