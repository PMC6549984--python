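"""Exception taxonomy.

Two broad families matter for the CLI exit codes: :class:`ValidationError`
(bad inputs or configuration, exit code 2) and :class:`ComputationError`
(a numerically well-posed request that failed during computation, exit
code 3).
"""

from __future__ import annotations


class LinprobError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LinprobError):
    """Invalid input data, configuration or arguments."""


class ComputationError(LinprobError):
    """A computation could not be completed."""


class InvalidOutcomeError(ValidationError):
    """Outcome column does not have exactly the two expected levels."""


class CovariateTypeError(ValidationError):
    """A covariate column is not numeric."""


class MissingDataError(ValidationError):
    """Missing covariate cells where complete data is required."""


class SingularDesignError(ComputationError):
    """Design matrix is rank deficient.

    Parameters
    ----------
    dependent_columns : list of str
        Names of columns that are linearly dependent on the preceding ones.
    """

    def __init__(self, dependent_columns):
        self.dependent_columns = list(dependent_columns)
        super().__init__(
            "design matrix is rank deficient; linearly dependent columns: "
            + ", ".join(map(str, self.dependent_columns))
        )


class OptimizationFailureError(ComputationError):
    """Iterative optimisation did not converge; carries the last iterate."""

    def __init__(self, message, last_beta=None):
        self.last_beta = last_beta
        super().__init__(message)


class InfeasibleBetaError(ValidationError):
    """A coefficient vector puts some linear predictor outside (-1, 1)."""


class DegenerateVarianceError(ComputationError):
    """A required variance is not strictly positive."""


class DegenerateCorrelationError(ValidationError):
    """|rho| >= 1 where an interior correlation is required."""


class SeparationError(ComputationError):
    """Perfect separation detected while fitting the logistic model."""


class NonOrthogonalDesignError(ValidationError):
    """Sensitivity pattern set does not form orthogonal main-effect contrasts."""


class CannotSetLevelsError(ValidationError):
    """Low/high levels cannot be derived for a variable (e.g. all missing)."""


class FeasibilityError(ComputationError):
    """Rejection sampling could not produce feasible covariate rows."""
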