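"""Exception types shared across the package."""


class InputError(ValueError):
    """Malformed or inconsistent user input (bad file, missing sample, ...)."""


class DegenerateAnalysisError(RuntimeError):
    """The analysis cannot proceed on this data (e.g. a CV fold with one class)."""
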