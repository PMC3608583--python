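"""Exception hierarchy shared across the package."""


class PmhcGrooveError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PmhcGrooveError):
    """A structure or trajectory file could not be parsed."""


class ParameterizationError(PmhcGrooveError):
    """A (residue, atom) pair is missing from the parameter table."""


class ShapeError(PmhcGrooveError):
    """Array shapes are inconsistent (e.g. trajectory vs topology atom counts)."""


class ConfigurationError(PmhcGrooveError):
    """A selection, compartment map or run configuration is invalid."""


class GeometryError(PmhcGrooveError):
    """A geometric operation received degenerate input."""


class NumericError(PmhcGrooveError):
    """A numeric precondition failed (non-PSD covariance, non-positive IC50, ...)."""


class InternalError(PmhcGrooveError):
    """An internal consistency check failed; indicates a bug, not bad input."""
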