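"""Exception hierarchy shared by all analysis stages.

Every error raised on bad user input derives from :class:`RerepKitError`
so the command-line layer can map them onto exit code 2.
"""


class RerepKitError(ValueError):
    """Base class for all rerep-kit validation and input errors."""


class InvalidConfigError(RerepKitError):
    """A parameter or configuration value is out of its legal range."""


class EmptyInputError(RerepKitError):
    """An operation that requires at least one record received none."""


class BinningMismatchError(RerepKitError):
    """Two tracks that must share binning do not."""


class DegenerateRangeError(RerepKitError):
    """A range-percentile stratification was requested on a constant track."""


class InvalidRecordError(RerepKitError):
    """A single measurement record violates its schema (e.g. negative fork length)."""


class InvalidTableError(RerepKitError):
    """A contingency table has a zero margin or negative counts."""


class TooFewDomainsError(RerepKitError):
    """Quartile stratification needs at least four domains."""


class UndefinedCorrelationError(RerepKitError):
    """Correlation requested on a constant input."""


class ParseError(RerepKitError):
    """A text input file is malformed; message carries the 1-based line number."""
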