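"""Exception hierarchy shared across the package."""


class SpecRankError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SpecRankError, ValueError):
    """A text file does not conform to the expected dialect."""


class SpectrumError(SpecRankError, ValueError):
    """A spectrum violates its invariants (empty, unsorted-unfixable, bad values)."""


class DomainError(SpecRankError, ValueError):
    """An input value lies outside the mathematically valid domain."""


class LibraryError(SpecRankError, ValueError):
    """Inconsistent spectral-library construction (duplicate or orphan ids)."""


class UndefinedScoreError(SpecRankError, ValueError):
    """A similarity score is undefined (e.g. a spectrum with all-zero intensities)."""


class ValidationError(SpecRankError, ValueError):
    """An identifier failed validation (e.g. a malformed InChIKey)."""


class ConfigError(SpecRankError, ValueError):
    """An infeasible or inconsistent synthetic-benchmark configuration."""
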