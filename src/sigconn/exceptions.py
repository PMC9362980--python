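"""Exception hierarchy for sigconn.

``SigconnError`` is the common base so callers can catch everything the
library raises deliberately.  ``ValidationError`` maps to CLI exit code 2.
"""


class SigconnError(Exception):
    """Base class for all sigconn errors."""


class ValidationError(SigconnError, ValueError):
    """Invalid input data or parameters supplied by the caller."""


class ParameterError(ValidationError):
    """A tuning parameter is out of its admissible range."""


class QueryTypeError(ValidationError):
    """The query object cannot be routed to the requested metric."""


class InsufficientOverlapError(ValidationError):
    """Too few shared genes between the query and a library signature."""


class UndefinedCorrelationError(SigconnError, ArithmeticError):
    """A correlation is undefined (zero variance in one of the vectors)."""


class InsufficientInformationError(ValidationError):
    """All correlation weights vanish; nothing left to score."""


class NoOverlapError(InsufficientOverlapError):
    """A gene-list query shares no gene with the signature."""


class DegenerateSetError(ValidationError):
    """A member set equals the whole universe; enrichment is undefined."""


class ParseError(SigconnError, ValueError):
    """A file does not conform to its declared format."""
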