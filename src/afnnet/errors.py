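"""Exception types shared across the package."""


class ContractViolation(ValueError):
    """An input violates an operation's documented precondition."""


class ConfigurationError(ValueError):
    """A configuration value is invalid or inconsistent."""


class DataLayoutError(ValueError):
    """An on-disk dataset does not match the expected layout."""
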