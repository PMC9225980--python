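"""Exception hierarchy for model configuration and numerical failures."""


class CrsensError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CrsensError, ValueError):
    """Invalid variant tag, parameter set, or gradient specification."""


class DomainError(CrsensError, ValueError):
    """State or parameter outside its mathematical domain (e.g. negative density)."""


class UnsupportedVariantError(CrsensError, ValueError):
    """Operation not defined for this model variant (e.g. closed-form equilibria of RMS)."""


class StaleEquilibriumError(CrsensError, ValueError):
    """A point presented as an equilibrium does not satisfy the model equations."""


class InfeasibleLinearizationError(CrsensError, ValueError):
    """Linearization requested at a non-interior (infeasible) equilibrium."""


class BifurcationNotFoundError(CrsensError, RuntimeError):
    """No bifurcation of the requested kind inside the scanned gradient range."""


class IntegrationError(CrsensError, RuntimeError):
    """Trajectory integration failed; carries the offending parameter value."""
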