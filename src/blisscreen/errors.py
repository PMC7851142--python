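"""Exception hierarchy for screen I/O, scoring and synergy analysis."""


class BlisscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BlisscreenError):
    """A file is structurally unusable (missing columns, bad header)."""


class RowValidationError(BlisscreenError):
    """One or more data rows failed field-level validation.

    Carries the offending 1-based file line numbers in ``lines``.
    """

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = list(lines or [])


class StructuralError(BlisscreenError):
    """Checkerboard replicates disagree on dose axes or lack the (0,0) anchor."""


class MissingReferenceError(BlisscreenError):
    """A plate has no usable non-targeting control wells."""


class DegenerateReferenceError(BlisscreenError):
    """All control wells on a plate counted zero cells."""


class DomainError(BlisscreenError):
    """An input value is outside the mathematical domain of an operation."""


class AmbiguityError(BlisscreenError):
    """A gene is represented by more than one pool reagent."""


class NoSolutionError(BlisscreenError):
    """The requested inhibition level lies outside the fitted response span."""
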