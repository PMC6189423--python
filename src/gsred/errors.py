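"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class GsredError(Exception):
    """Base class for all package errors."""


class ConfigError(GsredError):
    """Invalid configuration or degenerate parameter combination."""


class DataError(GsredError):
    """Malformed, inconsistent, or out-of-contract input data."""


class BoundsError(DataError):
    """A coordinate falls outside the object it indexes."""


class ProtectedBreakpointError(GsredError):
    """An operator would cut through a gene while gene protection is on."""
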