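"""Exception hierarchy for the package."""


class SemgloveError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SemgloveError, ValueError):
    """A configuration value violates its stated constraints."""


class MissingLabelsError(SemgloveError, ValueError):
    """An operation requiring per-sample labels got an unlabeled recording."""


class InsufficientDataError(SemgloveError, ValueError):
    """Not enough examples of some class to perform the requested split."""


class RecordingFormatError(SemgloveError, ValueError):
    """A recording file is malformed (wrong channels, bad header, bad time axis)."""


class ControlTimeoutError(SemgloveError, RuntimeError):
    """The pressure controller could not reach its target within the tick budget."""


class PipelineStageError(SemgloveError, RuntimeError):
    """A pipeline stage failed; the message names the stage and its input."""
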