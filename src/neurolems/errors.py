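"""Exception hierarchy shared across the toolkit.

Every error raised by neurolems derives from :class:`NeuroLemsError`, so
callers can catch one type at an API boundary.  Validation routines do not
raise; they return lists of :class:`Issue` records instead, because a
document with problems is still useful data.
"""

from __future__ import annotations

from dataclasses import dataclass


class NeuroLemsError(Exception):
    """Base class for all neurolems errors."""


class ParseError(NeuroLemsError):
    """Malformed input text: XML, JSON, SWC, a quantity, or an expression."""


class UnitError(NeuroLemsError):
    """Unknown unit symbol or a quantity used with the wrong dimension."""


class StructureError(NeuroLemsError):
    """Violated containment or tree-shape rules (LEMS elements, morphologies)."""


class ValidationError(NeuroLemsError):
    """A document failed validation at a point where validity is a precondition."""

    def __init__(self, message: str, issues=None):
        super().__init__(message)
        self.issues = list(issues or [])


class EvalError(NeuroLemsError):
    """Expression evaluation failed, e.g. an unbound identifier."""


class NumericError(NeuroLemsError):
    """A simulated state variable became non-finite."""


class UnsupportedError(NeuroLemsError):
    """The requested operation is outside a format's capability (lossy formats)."""


class UnresolvedReferenceError(NeuroLemsError):
    """A name (type, component, unit, segment ...) does not resolve."""


@dataclass(frozen=True)
class Issue:
    """One validation finding. ``severity`` is ``error``, ``warning`` or ``info``."""

    severity: str
    message: str
    location: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" [{self.location}]" if self.location else ""
        return f"{self.severity}: {self.message}{loc}"


def has_errors(issues) -> bool:
    return any(i.severity == "error" for i in issues)
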