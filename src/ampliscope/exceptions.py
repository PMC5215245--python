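"""Exception hierarchy for ampliscope."""


class AmpliscopeError(Exception):
    """Base class for all package-specific errors."""


class InputError(AmpliscopeError, ValueError):
    """Invalid user-supplied value (empty input, bad weights, schema violation)."""


class StructureError(AmpliscopeError, ValueError):
    """Structurally invalid taxonomy (cycle, dangling parent, missing root)."""


class UnknownTaxonError(AmpliscopeError, KeyError):
    """A taxid or name that cannot be resolved against the loaded taxonomy."""


class DataError(AmpliscopeError, ValueError):
    """Inconsistent data tables (e.g. ground truth that cannot be projected to a rank)."""
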