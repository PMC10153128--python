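"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input object violates a documented invariant."""


class FormatError(ValueError):
    """An on-disk container is missing required datasets or attributes."""
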