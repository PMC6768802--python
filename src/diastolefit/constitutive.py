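"""Transversely isotropic constitutive model of passive myocardium.

The tissue is modelled with the four-parameter Fung-type exponential
(Guccione) strain-energy function

    W = c1 (exp(Q) - 1),
    Q = c2 Eff^2 + c3 (Ess^2 + Enn^2 + 2 Esn^2) + c4 (2 Efs^2 + 2 Efn^2),

where E is the Green-Lagrange strain expressed in the local fiber (f),
sheet (s), sheet-normal (n) material frame, c1 carries units of kPa and
c2..c4 are dimensionless exponent coefficients.

Because (c1, c2, c3, c4) are strongly coupled in inverse problems, the law is
also carried in a reformulated parameterization that separates a homogeneous
stiffness scale from anisotropy fractions:

    alpha = c2 + c3 + c4,   r2 = c2/alpha,  r3 = c3/alpha,  r4 = c4/alpha,

with r2 + r3 + r4 = 1. The total second Piola-Kirchhoff stress combines the
passive (deviatoric) response, a hydrostatic term from incompressibility, and
a length-dependent active fiber tension:

    T = dW/dE + p C^-1 + Ta f (x) f,
    Ta = t_z (1 + beta (sqrt(2 Eff + 1) - 1)),

where C = 2E + I, t_z (kPa) is the combined reference-tension-times-activation
parameter and beta the linear length-dependence coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateParameterError, UnphysicalStrainError, ValidationError

__all__ = [
    "GuccioneParams",
    "ReformulatedParams",
    "GreenStrain",
    "StressState",
    "ActiveTensionModel",
    "reformulate",
    "restore",
    "exponent_q",
    "strain_energy",
    "passive_stress",
    "active_tension",
    "total_stress",
    "DEFAULT_BETA",
]

#: Default linear length-dependence coefficient of the active tension.
#: Follows the convention of the HMT family of active contraction models;
#: configurable everywhere it is used.
DEFAULT_BETA = 1.45

# Largest exponent Q accepted before the strain energy is declared to have
# overflowed (exp(50) ~ 5e21 kPa is far beyond any physical stress).
_Q_OVERFLOW = 500.0


@dataclass(frozen=True)
class GuccioneParams:
    """Original four-parameter form. ``c1`` in kPa, the rest dimensionless."""

    c1: float
    c2: float
    c3: float
    c4: float

    def __post_init__(self):
        if not (self.c1 > 0):
            raise ValidationError(f"c1 must be positive, got {self.c1}")
        for name in ("c2", "c3", "c4"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValidationError(f"{name} must be nonnegative, got {v}")
        if not (self.c2 + self.c3 + self.c4 > 0):
            raise DegenerateParameterError(
                "c2 + c3 + c4 must be positive (degenerate exponent)"
            )

    def as_dict(self) -> dict:
        return {"c1": self.c1, "c2": self.c2, "c3": self.c3, "c4": self.c4}


@dataclass(frozen=True)
class ReformulatedParams:
    """Scale/anisotropy form: ``alpha`` = c2+c3+c4, ``r2``+``r3``+``r4`` = 1."""

    c1: float
    alpha: float
    r2: float
    r3: float
    r4: float

    def __post_init__(self):
        if not (self.c1 > 0):
            raise ValidationError(f"c1 must be positive, got {self.c1}")
        if not (self.alpha > 0):
            raise DegenerateParameterError(f"alpha must be positive, got {self.alpha}")
        for name in ("r2", "r3", "r4"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValidationError(f"{name} must be nonnegative, got {v}")
        if abs(self.r2 + self.r3 + self.r4 - 1.0) >= 1e-12:
            raise ValidationError(
                f"anisotropy fractions must sum to 1, got {self.r2 + self.r3 + self.r4!r}"
            )

    def as_dict(self) -> dict:
        return {
            "c1": self.c1,
            "alpha": self.alpha,
            "r2": self.r2,
            "r3": self.r3,
            "r4": self.r4,
        }


def reformulate(g: GuccioneParams) -> ReformulatedParams:
    """Map (c1, c2, c3, c4) to (c1, alpha, r2, r3, r4)."""
    alpha = g.c2 + g.c3 + g.c4
    if alpha <= 0:
        raise DegenerateParameterError("c2 + c3 + c4 = 0: anisotropy undefined")
    r3, r4 = g.c3 / alpha, g.c4 / alpha
    # guard rounding so the r-sum and nonnegativity invariants hold exactly
    r2 = max(1.0 - r3 - r4, 0.0)
    return ReformulatedParams(c1=g.c1, alpha=alpha, r2=r2, r3=r3, r4=r4)


def restore(r: ReformulatedParams) -> GuccioneParams:
    """Inverse of :func:`reformulate`."""
    return GuccioneParams(
        c1=r.c1, c2=r.r2 * r.alpha, c3=r.r3 * r.alpha, c4=r.r4 * r.alpha
    )


@dataclass(frozen=True)
class GreenStrain:
    """Green-Lagrange strain components in the fiber/sheet/normal frame."""

    e_ff: float = 0.0
    e_ss: float = 0.0
    e_nn: float = 0.0
    e_sn: float = 0.0
    e_fn: float = 0.0
    e_fs: float = 0.0

    def __post_init__(self):
        for name in ("e_ff", "e_ss", "e_nn", "e_sn", "e_fn", "e_fs"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"strain component {name} is not finite")

    def tensor(self) -> np.ndarray:
        """Full symmetric 3x3 tensor in (f, s, n) ordering."""
        return np.array(
            [
                [self.e_ff, self.e_fs, self.e_fn],
                [self.e_fs, self.e_ss, self.e_sn],
                [self.e_fn, self.e_sn, self.e_nn],
            ]
        )

    @classmethod
    def from_tensor(cls, e: np.ndarray) -> "GreenStrain":
        e = np.asarray(e, dtype=float)
        if e.shape != (3, 3) or not np.allclose(e, e.T, atol=1e-10):
            raise ValidationError("Green strain must be a symmetric 3x3 tensor")
        return cls(
            e_ff=e[0, 0],
            e_ss=e[1, 1],
            e_nn=e[2, 2],
            e_sn=e[1, 2],
            e_fn=e[0, 2],
            e_fs=e[0, 1],
        )

    def right_cauchy_green(self) -> np.ndarray:
        """C = 2E + I; must be positive definite for a physical deformation."""
        return 2.0 * self.tensor() + np.eye(3)


@dataclass(frozen=True)
class StressState:
    """Second Piola-Kirchhoff stress (kPa) in the f/s/n frame plus the
    hydrostatic multiplier ``p`` (kPa)."""

    tensor: np.ndarray
    p: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (3, 3):
            raise ValidationError("stress tensor must be 3x3")
        if not np.allclose(t, t.T, atol=1e-9 * max(1.0, float(np.abs(t).max()))):
            raise ValidationError("stress tensor must be symmetric")
        object.__setattr__(self, "tensor", 0.5 * (t + t.T))


@dataclass(frozen=True)
class ActiveTensionModel:
    """Length-dependent active fiber tension.

    ``t_z`` is the combined reference tension times activation level (kPa);
    the two are never carried separately. ``beta`` scales the linear
    dependence on the fiber extension ratio sqrt(2 Eff + 1).
    """

    t_z: float = 0.0
    beta: float = DEFAULT_BETA

    def __post_init__(self):
        if not (self.beta >= 0):
            raise ValidationError(f"beta must be nonnegative, got {self.beta}")
        if not math.isfinite(self.t_z):
            raise ValidationError("t_z must be finite")


def exponent_q(e: GreenStrain, g: GuccioneParams) -> float:
    """Quadratic strain exponent Q (dimensionless, >= 0)."""
    return float(
        g.c2 * e.e_ff**2
        + g.c3 * (e.e_ss**2 + e.e_nn**2 + 2.0 * e.e_sn**2)
        + g.c4 * (2.0 * e.e_fs**2 + 2.0 * e.e_fn**2)
    )


def strain_energy(e: GreenStrain, g: GuccioneParams) -> float:
    """Strain-energy density W = c1 (exp(Q) - 1), kPa."""
    q = exponent_q(e, g)
    if q > _Q_OVERFLOW:
        raise UnphysicalStrainError(
            f"strain energy overflow: Q = {q:.3g} exceeds {_Q_OVERFLOW:g}"
        )
    return g.c1 * math.expm1(q)


def passive_stress(e: GreenStrain, g: GuccioneParams) -> StressState:
    """Deviatoric stress dW/dE in the f/s/n frame (kPa).

    The derivative is taken treating E as a full symmetric tensor, so the
    returned off-diagonal entries are true tensor components (the shear terms
    in Q carry explicit factors of 2 which cancel the 1/2 from symmetrizing).
    """
    q = exponent_q(e, g)
    if q > _Q_OVERFLOW:
        raise UnphysicalStrainError(
            f"passive stress overflow: Q = {q:.3g} exceeds {_Q_OVERFLOW:g}"
        )
    eq = math.exp(q)
    t = np.array(
        [
            [2.0 * g.c2 * e.e_ff, 2.0 * g.c4 * e.e_fs, 2.0 * g.c4 * e.e_fn],
            [2.0 * g.c4 * e.e_fs, 2.0 * g.c3 * e.e_ss, 2.0 * g.c3 * e.e_sn],
            [2.0 * g.c4 * e.e_fn, 2.0 * g.c3 * e.e_sn, 2.0 * g.c3 * e.e_nn],
        ]
    )
    return StressState(tensor=g.c1 * eq * t, p=0.0)


def active_tension(at: ActiveTensionModel, e_ff: float) -> float:
    """Length-dependent active tension Ta(Eff) in kPa."""
    ext_sq = 2.0 * e_ff + 1.0
    if ext_sq <= 0:
        raise UnphysicalStrainError(
            f"fiber extension ratio undefined: 2 Eff + 1 = {ext_sq:.3g} <= 0"
        )
    return at.t_z * (1.0 + at.beta * (math.sqrt(ext_sq) - 1.0))


def total_stress(
    e: GreenStrain, p: float, g: GuccioneParams, at: ActiveTensionModel
) -> StressState:
    """Total second Piola-Kirchhoff stress: passive + hydrostatic + active.

    The active part occupies only the fiber-fiber slot of the f/s/n frame.
    """
    c = e.right_cauchy_green()
    # positive definiteness check doubles as the invertibility guard
    try:
        np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        raise UnphysicalStrainError("2E + I is not positive definite") from None
    c_inv = np.linalg.inv(c)
    t = passive_stress(e, g).tensor + p * c_inv
    t[0, 0] += active_tension(at, e.e_ff)
    return StressState(tensor=t, p=p)
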