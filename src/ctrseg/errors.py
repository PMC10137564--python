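"""Exception hierarchy shared across the package."""


class CtrsegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CtrsegError, ValueError):
    """Invalid configuration or geometry parameters."""


class FormatError(CtrsegError, ValueError):
    """Unreadable or unsupported file format."""


class MaskValidationError(CtrsegError, ValueError):
    """A label mask contains values outside the allowed class set."""


class MissingStructureError(CtrsegError, ValueError):
    """A required anatomic class (heart or lung) has no pixels.

    Downstream this is the signal that an image needs human review
    rather than an automated CTR.
    """

    def __init__(self, structure: str, message: str | None = None):
        self.structure = structure
        super().__init__(message or f"no '{structure}' pixels present in mask")


class DegenerateInputError(CtrsegError, ValueError):
    """Statistical input with no usable variance (e.g. identical pairs)."""


class ConfigurationError(CtrsegError, ValueError):
    """Model/training configuration that cannot be realised."""
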