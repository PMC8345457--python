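"""Exception types shared across the package."""


class LagopopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LagopopError):
    """Invalid scenario, nest, landscape or parameter configuration."""


class DomainError(LagopopError, ValueError):
    """A numeric argument outside its mathematical domain."""


class DerivationError(LagopopError):
    """Dose-response derivation impossible from the given endpoints."""


class GeometryError(LagopopError):
    """Degenerate or inconsistent landscape geometry."""
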