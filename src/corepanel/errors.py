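"""Exception hierarchy for corepanel."""


class CorePanelError(Exception):
    """Base class for all corepanel errors."""


class VcfFormatError(CorePanelError):
    """The VCF (or genotype TSV) cannot be interpreted as genotype data."""


class InputError(CorePanelError):
    """Input data violates a precondition (e.g. duplicate sample IDs)."""


class ConfigError(CorePanelError):
    """A configuration value is outside its allowed range."""
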