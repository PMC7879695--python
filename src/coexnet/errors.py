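"""Typed error hierarchy.

Every reader and numeric stage raises one of these instead of a bare
ValueError, so callers (and the pipeline driver) can distinguish malformed
input from invalid analysis state.
"""


class CoexnetError(Exception):
    """Base class for all package errors."""


class FormatError(CoexnetError, ValueError):
    """A file or table violates its declared dialect (duplicate IDs,
    non-numeric cells, unknown biotype, short GMT line, ...)."""


class CoordinateError(FormatError):
    """A genomic interval violates the 0-based half-open convention."""


class ValidationError(CoexnetError, ValueError):
    """An in-memory object or argument violates a documented precondition."""


class StateError(CoexnetError, RuntimeError):
    """An operation was applied to data on the wrong scale or in the wrong
    pipeline state (e.g. log2-transforming an already-log2 matrix)."""


class DegenerateInputError(CoexnetError, ValueError):
    """A statistic is undefined for this input (e.g. zero-variance vector
    passed to a correlation)."""


class ConfigError(CoexnetError, ValueError):
    """A simulation or pipeline configuration is inconsistent or incomplete."""


class PipelineStageError(CoexnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
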