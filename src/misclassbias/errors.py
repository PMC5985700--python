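"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A scenario, grid, or configuration parameter violates its constraint."""
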