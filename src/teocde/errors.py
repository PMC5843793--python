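"""Exception hierarchy for teocde.

All package errors derive from :class:`TeoCdeError` so callers can catch
one base class; subclasses mark the failing stage (XML reading, duration
grammar, interval inference, pattern parsing, serialization, statistics).
"""


class TeoCdeError(Exception):
    """Base class for all teocde errors."""


class CdeXmlError(TeoCdeError):
    """A caDSR XML document is malformed or violates record invariants."""


class AnnotationError(TeoCdeError):
    """An annotation record or file violates the annotation schema."""


class DurationParseError(TeoCdeError):
    """A duration pattern string does not follow the compact or verbose grammar."""


class IncompleteIntervalError(TeoCdeError):
    """Too few concrete components to run interval or phase inference."""


class CommensurabilityError(TeoCdeError):
    """Calendar units (month/year) mixed into exact arithmetic."""


class OrderingError(TeoCdeError):
    """An interval's start time lies after its end time."""


class InconsistentPhaseError(TeoCdeError):
    """A fully specified time phase violates period = repeat unit + gap."""


class NormalizationError(TeoCdeError):
    """A time literal matched none of the configured formats."""


class PatternSyntaxError(TeoCdeError):
    """A pattern string is not well formed (unbalanced brackets etc.)."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (offset {offset})")
        self.offset = offset


class VocabularyError(TeoCdeError):
    """An unknown TEO class, property or temporal-relation name."""


class BindingError(TeoCdeError):
    """A pattern binding addresses a slot the template does not define."""


class IncompleteBindingError(TeoCdeError):
    """A fixed (static) template slot was left unbound."""


class GraphIntegrityError(TeoCdeError):
    """An RDF node graph references a node that is not part of the graph."""


class UndefinedStatisticError(TeoCdeError):
    """A statistic's denominator is zero (e.g. sensitivity with tp+fn=0)."""
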