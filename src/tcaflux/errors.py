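"""Exception hierarchy shared across the pipeline.

Every error raised on bad user input derives from :class:`TcafluxError`
so callers (and the CLI) can distinguish validation failures (exit 2)
from genuine bugs (exit 1).
"""


class TcafluxError(Exception):
    """Base class for all errors raised by tcaflux on invalid input."""


class ConfigurationError(TcafluxError):
    """A configuration is missing a required entry or holds an invalid value."""


class BalanceError(TcafluxError):
    """A flux network cannot be mass-balanced with nonnegative effluxes."""


class ValidationError(TcafluxError):
    """A data object (MID, table, matrix) violates its invariants."""


class DataError(TcafluxError):
    """Insufficient or malformed data for the requested computation."""


class DomainError(TcafluxError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class IntegrationError(TcafluxError):
    """The fixed-step integrator became unstable; retry with a smaller step."""
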