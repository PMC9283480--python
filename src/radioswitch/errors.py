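"""Exception hierarchy.

The CLI maps these onto distinct exit codes: configuration problems (3),
data problems (4), numerical failures (5).
"""


class RadioswitchError(Exception):
    """Base class for all package errors."""


class DomainError(RadioswitchError, ValueError):
    """An argument is outside its physical domain (negative dose, etc.)."""


class ConfigurationError(RadioswitchError):
    """Invalid preset, config file, or parameter combination."""


class DataError(RadioswitchError, ValueError):
    """Input data violates the assumptions of an estimator."""


class DataOrderingError(DataError):
    """A readout lies outside the open interval required by the transform."""


class InsufficientDataError(DataError):
    """Too few usable points remain for the requested fit."""


class PairingError(DataError):
    """A paired control series was required but not supplied."""


class DegenerateCompetitionError(DataError):
    """Scavenger competition with no scavenging capacity at all."""


class NumericalError(RadioswitchError):
    """A computation failed numerically (division by zero yield, etc.)."""
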