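"""Exception hierarchy shared across the package."""


class FoliarchemError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FoliarchemError):
    """A configuration value is invalid; the message names the offending field."""


class InputError(FoliarchemError):
    """Input data violates a precondition (empty spectrum, index mismatch, ...)."""


class InferenceError(FoliarchemError):
    """A statistical test cannot be computed (empty pair sets, exhausted redraws)."""


class RangeError(FoliarchemError):
    """A value falls outside the calibrated/interpolable range."""
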