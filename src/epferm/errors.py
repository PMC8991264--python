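"""Exception hierarchy.

Errors are grouped so callers (and the CLI) can distinguish usage problems,
bad data, and numerical failures without string matching.
"""


class EpfermError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EpfermError):
    """A required setting, range, or factor value is missing or malformed."""


class DataError(EpfermError):
    """Input data violate a schema or domain precondition."""


class NumericError(EpfermError):
    """A numerical procedure failed or produced an invalid result."""


# --- design of experiments ---------------------------------------------------

class CapacityError(ConfigurationError):
    """More factors requested than the design construction can carry."""


class InvalidGeneratorError(ConfigurationError):
    """A lattice generator is not coprime with the construction modulus."""


class FixtureIntegrityError(DataError):
    """The packaged design fixture fails its checksum or balance checks."""


class InsufficientGroupsError(DataError):
    """Fewer than two groups supplied to a group comparison."""


class DegenerateVarianceError(DataError):
    """Zero pooled variance with unequal group means."""


# --- response surface --------------------------------------------------------

class IncompleteDesignError(DataError):
    """The design has missing response cells."""


class UnderdeterminedError(DataError):
    """Fewer observations than model parameters."""


class CollinearityError(NumericError):
    """Model matrix is rank deficient or numerically singular."""

    def __init__(self, message, columns=()):
        super().__init__(message)
        self.columns = tuple(columns)


class NoStationaryPointError(NumericError):
    """Quadratic coefficient is zero; the parabola has no vertex."""


# --- kinetics ----------------------------------------------------------------

class KineticsDomainError(DataError):
    """State or measurement outside the model's admissible domain."""


class SingularityError(DataError):
    """Evaluation at a singular point (e.g. Contois rate at zero biomass)."""


class IntegrationFailureError(NumericError):
    """ODE integration did not converge or produced non-finite state."""


class InsufficientDataError(DataError):
    """Too few usable points for the requested fit."""


class ScheduleError(ConfigurationError):
    """Feed schedule inconsistent with the simulation horizon."""
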