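"""Exception types shared across the screening pipeline."""


class ExomodError(Exception):
    """Base class for all package errors."""


class ConfigError(ExomodError):
    """A simulation or analysis configuration is invalid."""


class SimulationError(ExomodError):
    """Synthetic-data generation could not satisfy its constraints."""

    def __init__(self, message: str, achieved: int | None = None):
        super().__init__(message)
        self.achieved = achieved


class InvalidWellError(ExomodError):
    """A well cannot be normalized (e.g. zero nuclei)."""


class MissingControlError(ExomodError):
    """No vehicle/control group is available for normalization."""


class DegenerateDataError(ExomodError):
    """Statistical input carries no usable variance."""


class UndefinedSeparationError(ExomodError):
    """Z'-factor is undefined because control means coincide."""
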