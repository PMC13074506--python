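"""Exception hierarchy shared across the package."""


class TeaspecError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TeaspecError):
    """A configuration object violates its invariants."""


class InputError(TeaspecError):
    """Operation input violates a precondition."""


class ParseError(TeaspecError):
    """A sample-table file could not be parsed into a valid table."""


class ScreeningError(TeaspecError):
    """Index screening cannot proceed (e.g. constant target)."""


class AssemblyError(TeaspecError):
    """Model-input assembly could not produce the required columns."""
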