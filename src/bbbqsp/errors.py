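"""Exception types shared across the simulator."""


class ValidationError(ValueError):
    """An input, parameter set, or state violates its declared contract."""


class ConfigError(ValidationError):
    """A scenario configuration failed schema or consistency validation."""
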