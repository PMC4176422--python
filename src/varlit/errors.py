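"""Exception hierarchy."""


class VarlitError(Exception):
    """Base class for all package errors."""


class NormalizationError(VarlitError):
    """A token or key could not be normalized; the message names the offender."""


class ConfigError(VarlitError):
    """Invalid recognizer / generator / dictionary configuration."""


class CorruptAnnotationError(VarlitError):
    """A standoff annotation does not agree with its document text."""


class FormatError(VarlitError):
    """A file does not conform to its declared tabular or standoff format."""
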