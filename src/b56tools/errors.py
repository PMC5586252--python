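"""Exception hierarchy shared across the package."""


class B56Error(Exception):
    """Base class for package-specific errors."""


class ParameterError(B56Error, ValueError):
    """A numeric or categorical parameter is outside its documented domain."""


class FormatError(B56Error, ValueError):
    """An input record (sequence, count table, annotation) is malformed."""


class CapacityError(B56Error, ValueError):
    """A synthetic construct does not fit in the available sequence space."""


class InsufficientDataError(B56Error, ValueError):
    """Too few observations to run the requested statistical procedure."""


class AlignmentError(B56Error, ValueError):
    """Motif-anchored alignment frame falls outside the peptides."""


class AnnotationError(B56Error, ValueError):
    """A per-residue annotation table does not cover the query sequence."""


class FitError(B56Error, RuntimeError):
    """A least-squares fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
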