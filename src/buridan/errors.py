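"""Exception hierarchy shared by all modules."""


class BuridanError(Exception):
    """Base class for all package errors."""


class ParseError(BuridanError):
    """A data file could not be parsed (message names the offending line)."""


class ValidationError(BuridanError):
    """Parsed content violates an invariant of its type."""


class DegenerateGeometryError(BuridanError):
    """A geometric construction has no solution (e.g. collinear points)."""
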