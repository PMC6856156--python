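"""Exception hierarchy for the package.

All errors raised deliberately by this package derive from
:class:`TwoSampleMRError`, so callers can catch the package's failures
without swallowing genuine bugs.
"""

from __future__ import annotations


class TwoSampleMRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TwoSampleMRError):
    """A run configuration or column mapping is unusable (missing column,
    missing file, instrument absent from the exposure file, ...)."""


class ValidationError(TwoSampleMRError):
    """Input data violate a stated invariant.

    Carries the full list of per-row messages so the caller sees every
    offending row, not just the first one encountered.
    """

    def __init__(self, errors: list[str] | str):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("\n".join(self.errors))


class HarmonizationError(TwoSampleMRError):
    """Misuse of the harmonization API (e.g. pairing records with
    different variant identifiers)."""


class EmptySetError(TwoSampleMRError):
    """No variants survived selection/harmonization, so no estimate exists."""


class UndefinedRatioError(TwoSampleMRError):
    """A Wald ratio was requested for a variant with zero exposure effect."""


class InsufficientInstrumentsError(TwoSampleMRError):
    """An estimator requires more instruments than the set provides."""


class CollinearityError(TwoSampleMRError):
    """The MR-Egger design matrix is singular (no variation in exposure betas)."""
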