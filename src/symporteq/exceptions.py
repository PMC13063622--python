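"""Package-specific exception types.

All inherit from ValueError (bad inputs) or RuntimeError (failed
computations) so callers can catch broadly or precisely.
"""


class UnsupportedStoichiometryError(ValueError):
    """Raised for non-electroneutral symport stoichiometries.

    Only electroneutral 1 H+ : 1 monovalent-anion coupling is modelled;
    charged transport would require a membrane-potential term that this
    equilibrium layer deliberately does not parameterise.
    """


class ExtrapolationError(ValueError):
    """Raised when a query pH lies outside the measured pH range."""


class InsufficientDataError(ValueError):
    """Raised when too few usable data points remain for an operation."""


class PlacementError(RuntimeError):
    """Raised when the synthetic image generator cannot place all cells."""


class IntegrationError(RuntimeError):
    """Raised when the chemostat ODE integration fails to converge."""
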