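"""Exception hierarchy for the silenttrack pipeline."""


class SilentTrackError(Exception):
    """Base class for all pipeline errors."""


class InvalidParameterError(SilentTrackError, ValueError):
    """A parameter violates an operation's contract."""


class TooShortInputError(SilentTrackError, ValueError):
    """Input shorter than the minimum the operation can process."""


class EmptyTrackError(SilentTrackError, ValueError):
    """A feature track has no usable frames."""


class FormatError(SilentTrackError, ValueError):
    """A file is not in the expected on-disk format."""


class NumericalError(SilentTrackError, RuntimeError):
    """A linear-algebra step failed; usually fixable by raising regularization."""
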