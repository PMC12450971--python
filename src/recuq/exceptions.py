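"""Exception hierarchy shared across the pipeline."""


class RecuqError(Exception):
    """Base class for all package-specific errors."""


class CohortSpecError(RecuqError, ValueError):
    """A generator or run configuration violates its invariants."""


class TableFormatError(RecuqError, ValueError):
    """A feature-table file or frame is malformed."""


class DegenerateDataError(RecuqError, ValueError):
    """Data cannot support the requested computation (e.g. one-class labels)."""
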