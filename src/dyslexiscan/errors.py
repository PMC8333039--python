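"""Exception hierarchy shared across the package."""


class DyslexiscanError(Exception):
    """Base class for all package errors."""


class ValidationError(DyslexiscanError):
    """A value or data structure violates a documented invariant."""


class FormatError(DyslexiscanError):
    """An on-disk file does not conform to the expected tabular layout."""


class ConfigError(DyslexiscanError):
    """A configuration value is missing, unknown or inconsistent."""


class InfeasibleFoldsError(DyslexiscanError):
    """The fold constraints cannot be satisfied for the given cohort."""
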