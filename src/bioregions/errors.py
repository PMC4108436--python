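"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError -> 3,
DegeneracyError -> 4.
"""


class BioregionsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BioregionsError):
    """Invalid configuration: missing columns, bad parameter values."""


class DataError(BioregionsError):
    """Input data violates a structural invariant (empty site, duplicate id)."""


class DegeneracyError(BioregionsError):
    """The computation is undefined on this input (e.g. two empty assemblages,
    a dendrogram too shallow for knee search)."""
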