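"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """A configuration value (column mapping, threshold, option) is invalid."""


class InputError(ValueError):
    """The supplied data cannot be used (empty table, missing variant, bad SE)."""
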