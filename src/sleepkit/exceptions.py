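"""Package-specific error types."""


class UndefinedIndexError(ValueError):
    """A sleep index is undefined for this hypnogram (zero denominator)."""


class DegenerateInputError(ValueError):
    """Statistical input is degenerate (e.g. all paired differences zero)."""


class ChannelNotFoundError(KeyError):
    """Requested EEG channel is absent from the recording."""
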