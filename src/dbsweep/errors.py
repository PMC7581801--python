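"""Exception hierarchy shared across the package."""


class DBSweepError(Exception):
    """Base class for all package errors."""


class DomainError(DBSweepError, ValueError):
    """An argument is outside the physically meaningful domain."""


class PrecisionError(DBSweepError, ValueError):
    """A discretization step is too coarse for the requested operation."""


class TitrationError(DBSweepError, RuntimeError):
    """Threshold titration failed to locate a qualifying amplitude."""


class CoverageError(DBSweepError, ValueError):
    """A trajectory does not cover the protocol windows it is analysed against."""


class ParseError(DBSweepError, ValueError):
    """A file failed validation on read."""
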