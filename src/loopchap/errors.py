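"""Exception hierarchy.

All package errors derive from :class:`LoopchapError` so callers can catch
one base class; fitting failures get their own subclass because the CLI maps
them to a distinct exit code.
"""


class LoopchapError(Exception):
    """Base class for all loopchap errors."""


class ScaleError(LoopchapError):
    """Invalid or incomplete hydropathy scale table."""


class SequenceError(LoopchapError):
    """Invalid amino-acid sequence or motif definition."""


class TraceError(LoopchapError):
    """Invalid kinetic trace (too short, non-increasing times, ...)."""


class FitConvergenceError(LoopchapError):
    """A curve fit or global fit failed to converge."""


class StageError(LoopchapError):
    """Pipeline stage failure; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
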