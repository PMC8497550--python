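"""Exception hierarchy. CLI maps these onto distinct exit codes."""


class TriprojError(Exception):
    """Base class for all package errors."""


class ParseError(TriprojError):
    """Malformed or empty input file."""


class DataError(TriprojError):
    """Inconsistent shapes, axes, or empty inputs."""


class NumericalError(TriprojError):
    """Divergence or other numerical failure during optimisation."""
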