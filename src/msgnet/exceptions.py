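class MsgnetError(Exception):
    """Base class for package errors."""


class ValidationError(MsgnetError, ValueError):
    """An input value violates a documented precondition (range, shape, labels)."""


class ConfigurationError(MsgnetError, ValueError):
    """A constant or configuration value makes the model degenerate."""
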