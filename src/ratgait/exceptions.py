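"""Exception hierarchy shared across the package."""


class RatGaitError(Exception):
    """Base class for all package errors."""


class ParameterError(RatGaitError, ValueError):
    """A generator or analysis parameter is outside its valid range."""


class InsufficientDataError(RatGaitError):
    """Too few events/samples/frames to compute the requested quantity."""


class FormatError(RatGaitError):
    """An input file or table does not conform to the expected layout."""


class ProtocolError(RatGaitError):
    """A von Frey session violates the up-down staircase rule."""


class NoContactError(RatGaitError):
    """No plate contact found in a force recording."""


class ConfigError(RatGaitError):
    """A run configuration value is invalid."""
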