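"""Exception hierarchy.

All package errors derive from :class:`DiastoleFitError` so callers (and the
CLI) can separate validation problems (exit code 2) from solver
non-convergence (exit code 3).
"""


class DiastoleFitError(Exception):
    """Base class for all diastolefit errors."""


class ValidationError(DiastoleFitError, ValueError):
    """Invalid inputs: bad parameter values, malformed files, shape mismatches."""


class DegenerateParameterError(ValidationError):
    """A constitutive parameter set collapses (e.g. alpha = c2+c3+c4 = 0)."""


class UnphysicalStrainError(DiastoleFitError):
    """A deformation state violates physical admissibility (2E + I not
    positive definite, overflowing strain energy, ...)."""


class NonConvergenceError(DiastoleFitError):
    """An iterative solve (equilibrium bracketing, deflation fixed point,
    sweep iteration) failed to converge within its configured budget."""

    def __init__(self, message: str, last_residual: float | None = None):
        super().__init__(message)
        self.last_residual = last_residual


class IllPosedFitError(DiastoleFitError):
    """A least-squares mesh fit is rank deficient (too few tracked points for
    the requested degrees of freedom). Consider more points or Tikhonov
    regularization."""


class CriterionError(DiastoleFitError):
    """No candidate reference frame satisfies the active-tension criterion."""

    def __init__(self, message: str, violations: dict | None = None):
        super().__init__(message)
        self.violations = violations or {}


class FormatError(ValidationError):
    """A file does not match the documented on-disk format."""
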