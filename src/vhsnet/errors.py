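"""Exception types shared across vhsnet modules."""


class VhsnetError(Exception):
    """Base class for all vhsnet errors."""


class DegenerateGeometryError(VhsnetError, ValueError):
    """A geometric quantity is undefined (e.g. zero-length vertebral segment EF)."""


class DomainError(VhsnetError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class FormatError(VhsnetError, ValueError):
    """A file or vector does not match the expected layout."""


class ConfigError(VhsnetError, ValueError):
    """A configuration value is inconsistent or out of range."""


class ShapeError(VhsnetError, ValueError):
    """An array shape is incompatible with the requested operation."""


class DivergenceError(VhsnetError, RuntimeError):
    """Training produced a non-finite loss."""
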