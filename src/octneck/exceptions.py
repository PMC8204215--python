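"""Exception hierarchy for octneck.

All package errors derive from :class:`OctNeckError` so callers can catch one
base class; subclasses mark which pipeline layer rejected the input.
"""


class OctNeckError(Exception):
    """Base class for all octneck errors."""


class CalibrationError(OctNeckError):
    """Acquisition geometry is missing or physically impossible."""


class FormatError(OctNeckError):
    """On-disk artifact does not match the expected layout."""


class ValidationError(OctNeckError):
    """In-memory object violates a data-model invariant."""


class AnnotationError(OctNeckError):
    """Wall/neck annotation is absent, degenerate, or inconsistent."""


class GeometryError(OctNeckError):
    """Coordinate transform asked for something outside its domain."""


class ConfigurationError(OctNeckError):
    """Parameter set violates its own invariants."""


class InputError(OctNeckError):
    """Operation input outside its precondition."""


class StageError(OctNeckError):
    """A pipeline stage failed; carries the stage name and case id."""

    def __init__(self, stage: str, case_id: str, cause: Exception):
        self.stage = stage
        self.case_id = case_id
        self.cause = cause
        super().__init__(f"stage '{stage}' failed for case '{case_id}': {cause}")
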