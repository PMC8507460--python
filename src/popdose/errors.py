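"""Exception hierarchy for the survey pipeline."""
from __future__ import annotations


class PopdoseError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PopdoseError):
    """A configuration value violates its invariant."""


class MappingError(PopdoseError):
    """Billing codes without an entry in the code map (strict mode)."""

    def __init__(self, codes):
        self.codes = sorted(set(codes))
        super().__init__(f"unmapped billing codes: {', '.join(map(str, self.codes))}")


class AmbiguousMergeError(PopdoseError):
    """Two merge rules claim the same component region within one session."""


class MissingResponseRateError(PopdoseError):
    """A surveyed modality has no response rate."""

    def __init__(self, modality):
        self.modality = modality
        super().__init__(f"no response rate configured for modality: {modality!r}")


class MissingConversionFactorError(PopdoseError):
    """A dose record region (or NM CT component) has no DLP-to-E factor."""


class ModalityMismatchError(PopdoseError):
    """Frequency and dose tables do not cover the same modalities."""
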