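"""Exception hierarchy.

``ConfigError`` marks problems with user-supplied configuration, ``DataError``
problems with the data itself; the CLI maps them to distinct exit codes.
"""


class RhodateError(Exception):
    """Base class for all package errors."""


class ConfigError(RhodateError):
    """Invalid configuration or parameter values."""


class DataError(RhodateError):
    """Input data violates a precondition (bad VCF, non-monophyletic clade, ...)."""


class InfiniteSitesError(ConfigError):
    """Requested mutation load exceeds the callable site universe."""
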