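"""Exception hierarchy shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition (wrong shape, sign, domain)."""


class ConfigurationError(ValidationError):
    """A simulation or analysis configuration is internally inconsistent."""


class DomainError(ValidationError):
    """A gestational age falls outside the reference-curve domain."""
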