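"""Exception hierarchy for input validation and degenerate statistics."""


class EpiScreenError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EpiScreenError):
    """A file violates the expected tabular layout (duplicate ids, bad header)."""


class ParseError(EpiScreenError):
    """A cell could not be parsed; carries row/column context in the message."""


class ValidationError(EpiScreenError):
    """A value violates a domain invariant (beta outside [0,1], time <= 0, ...)."""


class InsufficientDataError(EpiScreenError):
    """Too few observations to compute the requested statistic."""


class DegenerateDataError(EpiScreenError):
    """Data are constant/degenerate so the statistic is undefined."""
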