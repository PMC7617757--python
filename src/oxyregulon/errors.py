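"""Exception hierarchy shared across the pipeline stages."""


class OxyRegulonError(Exception):
    """Base class for package errors."""


class ConfigError(OxyRegulonError):
    """Invalid configuration: bad field values, inconsistent template options."""


class DataError(OxyRegulonError):
    """Invalid data: malformed track tables, empty analysis windows, bad traces."""


class ParseError(DataError):
    """A track file could not be parsed; the message names the offending column/line."""


class SimulationError(OxyRegulonError):
    """The ODE solver failed to converge or produced an invalid state."""
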