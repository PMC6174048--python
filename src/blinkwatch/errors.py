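"""Exception hierarchy shared across the package."""


class BlinkwatchError(Exception):
    """Base class for all package errors."""


class ParameterError(BlinkwatchError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(BlinkwatchError, ValueError):
    """Input data has the wrong shape, channel count or file grammar."""


class DegenerateImageError(BlinkwatchError, ValueError):
    """Image has no usable contrast (constant, or zero mean)."""


class BoundsError(BlinkwatchError, ValueError):
    """A rectangle or window falls outside the image."""


class ConfigError(BlinkwatchError, ValueError):
    """Pipeline or detector configuration is inconsistent."""


class TrainingError(BlinkwatchError, RuntimeError):
    """Optimization produced a non-finite loss."""


class InputError(BlinkwatchError, ValueError):
    """Missing or unreadable input files."""


class PipelineError(BlinkwatchError, RuntimeError):
    """End-to-end run aborted (e.g. detector failed on most frames)."""
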