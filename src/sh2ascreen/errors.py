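"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant.

    Maps to exit code 2 in the command-line interface.
    """
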