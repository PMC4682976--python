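"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A parameter set is internally inconsistent or out of range."""


class ValidationError(ValueError):
    """Input data violate a structural precondition."""
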