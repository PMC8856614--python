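"""Exception hierarchy for lnwire."""


class LnwireError(Exception):
    """Base class for all lnwire errors."""


class SchemaError(LnwireError, ValueError):
    """A table does not match the expected column schema."""


class IntegrityError(LnwireError, ValueError):
    """Data violate a uniqueness or consistency constraint."""


class ConfigError(LnwireError, ValueError):
    """A configuration value (bin edges, window sizes, ...) is invalid."""


class DegenerateTableError(LnwireError, ValueError):
    """A contingency table has an expected cell of zero."""
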