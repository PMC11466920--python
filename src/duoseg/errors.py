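"""Package exception hierarchy."""


class DuosegError(Exception):
    """Base class for package errors."""


class ShapeError(DuosegError, ValueError):
    """An input tensor has an inadmissible shape; the message names the dimension."""


class ConfigError(DuosegError, ValueError):
    """An architectural or training configuration is inconsistent."""


class GenerationError(DuosegError, RuntimeError):
    """The phantom generator could not satisfy the requested geometry."""
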