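"""Exception types shared across the package."""


class DyadsyncError(Exception):
    """Base class for package errors."""


class ValidationError(DyadsyncError, ValueError):
    """Invalid user-supplied value or malformed input data."""


class ConfigError(DyadsyncError, ValueError):
    """Inconsistent or impossible configuration."""


class StageError(DyadsyncError, ValueError):
    """Operation applied to a recording in the wrong processing stage."""
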