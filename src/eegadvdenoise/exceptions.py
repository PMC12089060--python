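"""Exception hierarchy for eegadvdenoise.

All package errors derive from :class:`EEGDenoiseError` so callers can catch
everything with one clause; the subclasses distinguish malformed files from
misuse of the API and from degenerate signal content.
"""


class EEGDenoiseError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EEGDenoiseError):
    """A file does not conform to the expected CSV/TSV dialect."""


class ParseError(FormatError):
    """A cell that should be numeric could not be parsed."""


class UsageError(EEGDenoiseError):
    """An operation was called on data that cannot support it."""


class EmptySelectionError(EEGDenoiseError):
    """A filtering step removed every sample/channel/window."""


class ShapeError(EEGDenoiseError):
    """An array does not meet a model's shape requirement."""


class DivergenceError(EEGDenoiseError):
    """Training produced a non-finite loss; the partial trace is attached."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
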