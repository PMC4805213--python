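"""Exception hierarchy shared across the package."""


class TallStatureError(Exception):
    """Base class for all package errors."""


class ValidationError(TallStatureError, ValueError):
    """An input value violates a documented precondition."""


class AgeOutOfRangeError(TallStatureError, ValueError):
    """Requested age lies outside a reference curve's grid; no extrapolation."""


class DomainError(TallStatureError, ValueError):
    """A mathematically undefined request (e.g. LMS inverse outside its domain)."""


class ParseError(TallStatureError, ValueError):
    """A reference or record table could not be parsed; carries row context."""


class IncompleteDataError(TallStatureError, ValueError):
    """Required clinical inputs are missing, so a rule cannot be evaluated."""
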