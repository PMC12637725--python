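"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An invalid configuration value (bad fold, empty panel, unknown key...)."""


class SchemaError(ValueError):
    """An on-disk table does not match the documented schema."""


class ReferentialIntegrityError(ValueError):
    """Cross-file references are inconsistent (e.g. dangling cell ids)."""
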