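"""Exception hierarchy used across the package."""

from __future__ import annotations


class LactospecError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LactospecError, ValueError):
    """An argument or data structure violates a documented invariant."""


class FormatError(LactospecError, ValueError):
    """A file could not be parsed as the expected wide-CSV spectra layout."""


class DegenerateSampleError(LactospecError, ValueError):
    """A scatter-correction fit produced a vanishing multiplicative term."""


class RankExhaustedError(LactospecError, ValueError):
    """PLS deflation ran out of covariance before the requested component.

    ``n_achievable`` is the number of latent variables that could be
    extracted before the residual cross-covariance vanished.
    """

    def __init__(self, message: str, n_achievable: int):
        super().__init__(message)
        self.n_achievable = int(n_achievable)


class PipelineStageError(LactospecError, RuntimeError):
    """An end-to-end run failed; carries the name of the failing stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
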