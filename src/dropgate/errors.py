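"""Exception hierarchy for dropgate."""


class DropgateError(Exception):
    """Base class for all dropgate errors."""


class FormatError(DropgateError):
    """Malformed input data (missing columns, non-numeric cells, ...)."""


class NamingError(DropgateError):
    """A filename does not contain a recognisable well token."""


class ClassificationError(DropgateError):
    """A gating operation cannot proceed (degenerate input, empty cluster, ...)."""


class NumericalError(DropgateError):
    """A numerical operation failed (e.g. singular cluster covariance)."""


class SaturationError(DropgateError):
    """All accepted droplets are positive; the Poisson estimate is unbounded."""


class EmptyWellError(DropgateError):
    """A well has no accepted droplets to quantify."""
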