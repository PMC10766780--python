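"""Exception hierarchy shared across the package."""


class AirscreenError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AirscreenError, ValueError):
    """A configuration or input value is out of range; the message names the field."""


class EmptyUniverseError(AirscreenError):
    """No annotated gene from the requested term is present in the expression matrix."""


class UndefinedScoreError(AirscreenError):
    """A score was requested for an empty interactor set."""


class NoSignalError(AirscreenError):
    """A trace has no variance left after detrending; no frequency can be estimated."""


class StageError(AirscreenError):
    """A pipeline stage failed; wraps the underlying error with the stage name."""
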