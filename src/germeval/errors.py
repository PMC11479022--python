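"""Exception hierarchy shared across the package."""


class GermevalError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GermevalError):
    """A trait scheme is malformed or an input table does not match it."""


class TableValidationError(GermevalError):
    """An accession table violates the scheme (bad label, duplicate id, ...)."""


class DegenerateScaleError(GermevalError):
    """A quantitative trait has zero spread, so sigma-binning is undefined."""


class PipelineStageError(GermevalError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
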