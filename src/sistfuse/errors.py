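"""Exception types shared across the package."""


class SistFuseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SistFuseError, ValueError):
    """An invalid parameter or configuration value."""


class InputError(SistFuseError, ValueError):
    """Invalid input data (shape mismatch, wrong range, empty input)."""


class StructureError(SistFuseError, ValueError):
    """Structurally inconsistent intermediate objects (pyramid/config mismatch)."""


class FormatError(SistFuseError, ValueError):
    """Unreadable or unsupported image file."""
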