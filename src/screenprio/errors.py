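"""Exception hierarchy for screenprio.

All library errors derive from :class:`ScreenPrioError` so callers (and the
CLI) can distinguish validation problems from genuine bugs.
"""


class ScreenPrioError(Exception):
    """Base class for all screenprio errors."""


class FormatError(ScreenPrioError):
    """An input file does not conform to its declared format."""


class EmptyCollectionError(ScreenPrioError):
    """A reference collection contains no usable records."""


class ConfigurationError(ScreenPrioError):
    """A parameter combination is invalid or yields a degenerate state."""


class ColdStartError(ScreenPrioError):
    """Training requested before both an inclusion and an exclusion exist."""


class DecisionConflictError(ScreenPrioError):
    """A screening decision was recorded twice for the same reference."""


class QueryParseError(ScreenPrioError):
    """A Boolean keyword query could not be parsed.

    Attributes
    ----------
    position : int
        Zero-based character offset of the first offending token.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UndefinedMetricError(ScreenPrioError):
    """A screening metric is undefined for the given trace (e.g. R = 0)."""
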