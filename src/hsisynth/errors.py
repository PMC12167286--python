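"""Typed exceptions: invariant violations never pass silently."""


class HsiError(Exception):
    """Base class for package errors."""


class ValidationError(HsiError):
    """Data violates a documented invariant (negative reflectance, bad labels...)."""


class FormatError(HsiError):
    """A file on disk is malformed or internally contradictory."""


class GenerationError(HsiError):
    """The phantom generator could not satisfy its constraints."""


class ConfigError(HsiError):
    """A configuration value is invalid or inconsistent."""
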