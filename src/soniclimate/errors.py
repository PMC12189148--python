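"""Exception hierarchy shared by all stages."""


class SonicError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SonicError, ValueError):
    """Raised for malformed data passed to an analysis stage."""


class InvalidConfigError(SonicError, ValueError):
    """Raised for inconsistent parameters or appraisal configuration."""


class AudioIOError(SonicError, IOError):
    """Raised when an audio or result file cannot be read or written."""
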