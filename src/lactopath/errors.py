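"""Exception types shared across the package."""


class LactopathError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(LactopathError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class ParseError(LactopathError, ValueError):
    """A text input (GMT, CSV) is malformed; message names the offending line."""


class NoStainError(LactopathError, RuntimeError):
    """Raised when an image carries too little optical density to fit a stain model."""
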