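"""Exception hierarchy."""


class LamellipidError(Exception):
    """Base class for all package errors."""


class ParseError(LamellipidError):
    """Malformed input file; message names the offending line where possible."""


class GeometryError(LamellipidError):
    """Invalid box, wrapped coordinates where unwrapped are required, etc."""


class SelectionError(LamellipidError):
    """Empty or invalid atom selection."""


class FitError(LamellipidError):
    """Nonlinear fit failed to converge after all restarts."""


class ConfigError(LamellipidError):
    """Invalid run configuration."""
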