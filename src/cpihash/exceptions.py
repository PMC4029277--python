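"""Typed exceptions raised across the package.

Everything derives from :class:`CpiHashError` so callers can catch the
package's failures with one clause while still distinguishing parse
problems from semantic ones.
"""


class CpiHashError(Exception):
    """Base class for all package errors."""


class ValidationError(CpiHashError, ValueError):
    """An argument or data structure violates a documented invariant."""


class ParseError(CpiHashError, ValueError):
    """A text table could not be parsed; the message names the line."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptySetError(CpiHashError, ValueError):
    """Minwise hashing of an empty feature set is undefined.

    Carries the offending (compound_id, protein_id) pair when known.
    """

    def __init__(self, message: str, pair: tuple[str, str] | None = None):
        super().__init__(message)
        self.pair = pair


class UndefinedSimilarityError(CpiHashError, ValueError):
    """Jaccard similarity of two empty sets is undefined."""


class DegenerateProblemError(CpiHashError, ValueError):
    """A training problem has no usable solution (e.g. one class only)."""


class ModeError(CpiHashError, ValueError):
    """An operation was applied to a model in the wrong feature mode."""


class UndefinedAUCError(CpiHashError, ValueError):
    """AUC is undefined when only one class is present."""


class GenerationError(CpiHashError, ValueError):
    """The synthetic generator cannot realize the requested configuration."""
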