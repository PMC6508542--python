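"""Exception hierarchy shared across the package."""


class LeafmorphError(Exception):
    """Base class for all package errors."""


class FormatError(LeafmorphError):
    """A file or stream does not conform to the expected dialect."""


class ValidationError(LeafmorphError):
    """An input violates a documented precondition or invariant."""


class DegenerateShapeError(ValidationError):
    """A configuration or outline is geometrically degenerate
    (coincident points, zero extent, too few vertices)."""
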