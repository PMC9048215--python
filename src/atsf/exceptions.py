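"""Exception hierarchy for the atsf package."""


class AtsfError(Exception):
    """Base class for all package errors."""


class ParseError(AtsfError):
    """A structure file could not be parsed; the message names the offending line."""


class ValidationError(AtsfError):
    """A molecule violated a structural invariant (e.g. disconnected bond graph)."""


class TypingError(AtsfError):
    """An atom name is not covered by the typing template."""


class GeometryError(AtsfError):
    """Degenerate geometry (collinear points, undefined dihedral, planar ring phase)."""


class EmbeddingError(AtsfError):
    """Ring closure / conformer embedding failed to reach its targets."""


class LayoutMismatchError(AtsfError):
    """A descriptor matrix does not match the layout a model was trained with."""


class UndefinedCorrelationError(AtsfError):
    """A correlation was requested for a zero-variance series."""
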