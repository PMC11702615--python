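"""Exception types shared across the package."""


class FormatError(ValueError):
    """An input file does not conform to its declared format."""


class ConfigurationError(ValueError):
    """A configuration value is invalid or internally inconsistent."""


class NoSignificantGenesError(ValueError):
    """No gene passed the significance threshold; downstream correlation is undefined."""
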