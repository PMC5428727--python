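"""Exception types shared across the package."""


class EcgFormatError(ValueError):
    """A file could not be parsed as the expected ECG format."""


class DegenerateSignalError(ValueError):
    """The input signal is too short or otherwise degenerate for the operation."""
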