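"""Exception hierarchy for gutsound.

Every error raised deliberately by the package derives from
:class:`GutsoundError`, so callers (and the CLI) can distinguish our
diagnostics from genuine bugs.
"""


class GutsoundError(Exception):
    """Base class for all gutsound errors."""


class ValidationError(GutsoundError, ValueError):
    """A domain object violated one of its invariants.

    The message names the offending field.
    """


class AudioFormatError(GutsoundError, ValueError):
    """A WAV file is missing, truncated, or uses an unsupported codec."""


class EmptyAudioError(AudioFormatError):
    """A WAV file decoded to zero samples."""


class LabelParseError(GutsoundError, ValueError):
    """A label-track line could not be parsed; message carries the line number."""


class ConfigError(GutsoundError, ValueError):
    """Inconsistent pipeline configuration (geometry mismatch, bad fold count...)."""
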