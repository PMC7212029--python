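"""Exception hierarchy shared across the package.

Three failure categories are distinguished so callers (and the CLI) can
map them to sensible exit behaviour: malformed on-disk inputs, invalid
configuration, and data that is structurally fine but statistically
unusable (e.g. a zero-variance gene).
"""


class WntStratError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WntStratError):
    """An on-disk file violates its format contract (bad header, duplicate
    identifier, non-numeric cell, unknown vocabulary token, ...)."""


class ConfigError(WntStratError):
    """A configuration value is invalid or inconsistent."""


class DataError(WntStratError):
    """Input data cannot support the requested computation (empty group,
    zero variance, missing gene, ...)."""
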