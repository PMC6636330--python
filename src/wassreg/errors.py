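"""Exception hierarchy shared across the package."""


class WassregError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(WassregError, ValueError):
    """Operands have incompatible shapes."""


class BalanceError(WassregError, ValueError):
    """Balanced optimal transport requires equal, positive total mass."""


class ConfigError(WassregError, ValueError):
    """Invalid hyper-parameter or configuration value."""


class ValidationError(WassregError, ValueError):
    """Input data violate a documented precondition."""


class SolverError(WassregError, RuntimeError):
    """An underlying numerical solver failed."""
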