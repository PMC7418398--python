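"""Exception hierarchy shared across the toolkit."""


class PqtlError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(PqtlError):
    """A configuration value is out of range or inconsistent."""


class InputValidationError(PqtlError):
    """An input table or file violates its contract."""


class DomainError(PqtlError):
    """A computation was requested outside its mathematical domain."""
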