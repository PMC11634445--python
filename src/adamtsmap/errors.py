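"""Exception types shared across the package.

Every error raised for a contract violation carries a short machine-readable
``code`` (e.g. ``"region_too_short"``) so that callers and the CLI can match
on it without parsing prose.
"""

from __future__ import annotations


class AdamtsMapError(ValueError):
    """Base class for all domain errors raised by this package."""

    def __init__(self, code: str, message: str | None = None):
        self.code = code
        super().__init__(f"{code}: {message}" if message else code)


class DesignError(AdamtsMapError):
    """Peptide-library design errors (bad regions, name collisions...)."""


class ElisaError(AdamtsMapError):
    """Plate-processing errors (missing blanks, bad standards...)."""


class AssayError(AdamtsMapError):
    """Mixing-study / Bethesda titration errors."""


class CohortError(AdamtsMapError):
    """Synthetic-cohort generation errors."""


class PipelineStageError(AdamtsMapError):
    """Raised by the orchestrator; wraps a stage name and the original error."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        code = getattr(original, "code", type(original).__name__)
        super().__init__(code, f"stage '{stage}' failed: {original}")
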