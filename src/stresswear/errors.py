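"""Exception hierarchy shared across the pipeline stages."""


class StresswearError(Exception):
    """Base class for all pipeline errors."""


class FormatError(StresswearError):
    """A file does not follow the expected on-disk dialect."""


class SchemaError(StresswearError):
    """A table's columns do not match the expected schema."""


class ValidationError(StresswearError):
    """A value violates a domain invariant (e.g. non-positive rate)."""


class RangeError(ValidationError):
    """A value lies outside its admissible range."""


class OrderingError(ValidationError):
    """Timestamps are not strictly increasing."""


class InsufficientDataError(StresswearError):
    """Too few (non-missing) samples for the requested operation."""


class AlignmentError(StresswearError):
    """Channel time spans do not overlap."""


class CoverageError(StresswearError):
    """A window has no stress-trace points (or no segment windows)."""


class StratificationError(StresswearError):
    """A class has fewer members than the requested fold count."""


class UnsupportedModelError(StresswearError):
    """The model does not expose the tree structure MDI needs."""
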