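"""Exception hierarchy shared across the package.

Configuration problems (bad parameter values, impossible settings) raise
:class:`ConfigError`; malformed or insufficient input data raises
:class:`DataError`.  The CLI maps these to exit codes 1 and 2.
"""


class CardiotouchError(Exception):
    """Base class for package-specific errors."""


class ConfigError(CardiotouchError, ValueError):
    """A configuration field is invalid.  The message names the field."""


class DataError(CardiotouchError, ValueError):
    """Input data are malformed or insufficient for the requested operation."""
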