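"""Exception hierarchy shared by all diaet modules."""


class DiaetError(Exception):
    """Base class for all errors raised by this package."""


class KBLoadError(DiaetError):
    """The knowledge-base file could not be read."""


class TurtleParseError(DiaetError):
    """The RDF document is not syntactically valid Turtle (subset).

    The message always names the 1-based line of the offending token.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(DiaetError):
    """A configuration object violates its contract (bad weight, bad bound, ...)."""


class DegenerateWeightsError(ValidationError):
    """All sibling weights are zero, so normalization is undefined."""


class DataError(DiaetError):
    """Evidence records are inconsistent (unit mismatch, count > arm size, ...)."""


class NoEvidenceError(DiaetError):
    """Signal: an aggregation was requested over an empty premise list."""


class TemplateError(DiaetError):
    """A verbalization template references an unresolvable placeholder."""


class StructuralError(DiaetError):
    """Two argument trees built from different dimension trees were compared."""


class UsageError(DiaetError):
    """An API entry point was called with an unsupported option."""
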