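"""Exception types shared across the package."""


class SitmotifError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SitmotifError, ValueError):
    """A file or table does not match the expected schema."""


class ConfigError(SitmotifError, ValueError):
    """An invalid configuration or parameter combination."""


class StratificationError(SitmotifError, RuntimeError):
    """A cross-validation fold could not be stratified (a class is too rare)."""
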