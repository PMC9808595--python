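"""Exception types shared across the package."""


class PbscreenError(Exception):
    """Base class for all package-specific errors."""


class SizingError(PbscreenError):
    """Requested synthetic genome cannot hold the requested genes."""


class DomainError(PbscreenError):
    """Input violates a documented precondition (e.g. no TTAA sites)."""


class ValidationError(PbscreenError):
    """A value is outside its documented domain."""


class ConfigError(PbscreenError):
    """A configuration object is internally inconsistent."""


class SchemaError(ConfigError):
    """A pipeline config contains an unknown or ill-typed key."""


class ParseError(PbscreenError):
    """An input file could not be parsed."""


class ConvergenceError(PbscreenError):
    """An iterative fit failed to converge (e.g. monotone Cox likelihood)."""
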