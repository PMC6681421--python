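"""Exception hierarchy shared across the package."""


class AlfkrigError(Exception):
    """Base class for all package errors."""


class ParseError(AlfkrigError):
    """Malformed input file; message carries the offending line number."""


class ConnectivityError(AlfkrigError):
    """Bond inference produced a graph unusable for local-frame work."""


class DegenerateFrameError(AlfkrigError):
    """Atomic local frame cannot be built (collinear or missing neighbors)."""


class SchemaError(AlfkrigError):
    """Tabular input missing required columns or mismatched shapes."""


class RoutingError(AlfkrigError):
    """No model registered for a requested tripeptide key."""
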