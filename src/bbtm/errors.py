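"""Exception hierarchy for the bbtm toolkit."""


class BbtmError(Exception):
    """Base class for all toolkit errors."""


class ParseError(BbtmError):
    """A file could not be parsed; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class AlignmentError(BbtmError):
    """Sequences do not form a valid multiple alignment."""


class TreeError(BbtmError):
    """A phylogenetic tree is structurally invalid."""


class AnnotationError(BbtmError):
    """A transmembrane-segment annotation is inconsistent."""


class ModelError(BbtmError):
    """A substitution-model object violates its invariants."""


class EstimationError(BbtmError):
    """MCMC estimation failed or produced a degenerate chain."""
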