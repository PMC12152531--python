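"""Exception hierarchy shared across the pipeline."""


class FibrilGoldError(Exception):
    """Base class for all pipeline errors."""


class AnnotationFormatError(FibrilGoldError, ValueError):
    """An input table is structurally unusable (missing column, bad dialect)."""


class AnnotationParseError(FibrilGoldError, ValueError):
    """A cell could not be parsed; the message carries the file row number."""


class ValidationError(FibrilGoldError, ValueError):
    """Parsed data violates an invariant (duplicate ids, zero-length fibril, ...)."""


class DegenerateDataError(FibrilGoldError, ValueError):
    """A statistic is undefined on the given data (e.g. all observations equal)."""
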