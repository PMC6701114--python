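"""Exception hierarchy for the screening pipeline.

Errors are split by contract: bad files (:class:`InputError`), data that
parses but violates domain invariants (:class:`ValidationError`),
misconfiguration (:class:`ConfigurationError`), per-pair numerical
degeneracy (:class:`DegenerateFitError`, :class:`InsufficientDataError`)
and cross-artifact integrity (:class:`IntegrityError`).
"""


class OmescreenError(Exception):
    """Base class for all package errors."""


class InputError(OmescreenError):
    """A file or argument could not be read in the documented dialect."""


class ValidationError(OmescreenError):
    """Parsed data violates a domain invariant (range, uniqueness, ...)."""


class ConfigurationError(OmescreenError):
    """A run configuration value is inconsistent with the data."""


class ContractError(OmescreenError):
    """An operation was invoked outside its contract."""


class DegenerateFitError(OmescreenError):
    """A pair's regression cannot be fit (singular design, constant response)."""

    def __init__(self, message: str, reason: str = "degenerate"):
        super().__init__(message)
        self.reason = reason


class InsufficientDataError(OmescreenError):
    """Too few samples (overall or within a cohort) to fit the pair."""


class IntegrityError(OmescreenError):
    """Cross-references between artifacts are inconsistent."""


class GenerationError(OmescreenError):
    """A synthetic-data specification produces unusable data."""
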