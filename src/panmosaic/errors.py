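"""Exception hierarchy."""


class PanmosaicError(Exception):
    """Base class for all package errors."""


class InputError(PanmosaicError):
    """Invalid user-supplied value or degenerate input."""


class ConfigError(PanmosaicError):
    """Inconsistent configuration."""


class SimulationError(PanmosaicError):
    """Panel simulation could not satisfy its placement constraints."""


class ParseError(PanmosaicError):
    """Malformed input file; carries the offending line number when known."""


class ConsistencyError(PanmosaicError):
    """Internal cross-references (coordinates, chromosomes) do not agree."""
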