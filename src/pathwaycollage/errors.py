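"""Exception hierarchy.

All anticipated user-facing failures derive from :class:`CollageError` so the
CLI can map them to exit code 1; anything else is an internal error (exit 2).
"""


class CollageError(Exception):
    """Base class for all expected errors raised by this package."""


class FormatError(CollageError):
    """Malformed input file (bad JSON, bad TSV shape, truncated collage)."""


class SchemaVersionError(FormatError):
    """A file declares a schema version this build does not understand."""


class CollectionValidationError(CollageError):
    """A pathway collection violates one or more domain invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations)
        super().__init__(f"collection failed validation: {lines}")


class EntityNotFoundError(CollageError, LookupError):
    """A referenced uid / compound / reaction / pathway does not exist."""


class StructuralError(CollageError):
    """A pathway's link/participant structure cannot be resolved to a chain."""


class SizingError(CollageError):
    """Requested collage width cannot accommodate the layouts."""


class ConflictError(CollageError):
    """Attempt to add an element that already exists."""


class MergeError(CollageError):
    """Invalid merge request (mixed compounds, too few nodes)."""


class OverlayModeError(CollageError):
    """Dataset column count does not match the requested overlay mode."""


class EditScriptError(CollageError):
    """An edit script contains an unknown op or bad arguments."""

    def __init__(self, index, message):
        self.index = index
        super().__init__(f"edit script step {index}: {message}")
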