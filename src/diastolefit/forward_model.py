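"""Reduced-order left-ventricular inflation and deflation operators.

The LV wall is an idealized axisymmetric truncated thick-walled ellipsoid.
Material shells are indexed by a transmural coordinate ``lam`` in [0, 1]
(0 = endocardium, 1 = epicardium) with equatorial semi-axis
``a(lam) = a_endo + lam*h`` and long semi-axis ``c(lam) = c_endo + lam*h``
(h = wall thickness, mm). The wall is cut by a fixed base plane at
``z = z_base`` and closed at the apex; a rule-based fiber field rotates
linearly across the wall from the endocardial to the epicardial helix angle
(default +60 deg to -60 deg), the sheet direction is transmural and the
sheet-normal completes the right-handed triad.

Deformation ansatz
------------------
Loaded configurations live in a low-dimensional Rayleigh-Ritz family.
Writing ``rho`` for the reference cylindrical radius, ``zbar = z/c_endo``
and ``eps = max(0, 1 - zbar^2)``, the map combines a slice-wise radial
motion with a slice-wise rigid rotation (ventricular torsion), both at a
fixed axial coordinate:

    rho'^2  = rho^2 + g(z),            g(z)  = sum_m q_m G_m(z),
    theta'  = theta + psi(z),          psi(z) = sum_m t_m Psi_m(z),
    z'      = z,

with G_m = zbar^j eps^p for (j, p) in {0, 1} x {3/2, 5/2, 7/2} (six radial
DOFs, mm^2) and Psi_m = ((z_base - z)/c_endo)^m for m in {1, 2} (two twist
DOFs, radians, vanishing at the base plane). Neither g nor psi depends on
``rho``, so each slice map conserves area: det F = 1 pointwise and exactly,
the tissue is incompressible by construction, and the hydrostatic stress
does no work under variations of the DOFs. The base plane and the apex are
fixed, every radial basis function decays at least like eps^(3/2) so the
deformation gradient stays bounded at the apex, and the transmurally
rotating fiber helix makes the equilibrium twist a sensitive probe of the
anisotropy split — the eight-dimensional observation overdetermines the
constitutive parameters from a single frame, which the estimation pipeline
relies on.

Equilibrium is the eight-equation virtual-work balance

    sum_g w_g (S_passive + Ta f (x) f) : dE/dq_m = P dV_cav/dq_m,

(the cavity volume is exactly linear in the radial DOFs and twist neutral)
solved by damped Newton with load stepping and warm starts. All lengths are
mm, stresses kPa, volumes ml. Everything is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .constitutive import ActiveTensionModel, GreenStrain, GuccioneParams
from .exceptions import (
    NonConvergenceError,
    UnphysicalStrainError,
    ValidationError,
)

__all__ = [
    "UnloadedGeometry",
    "MaterialPointSet",
    "LoadState",
    "BoundaryConditions",
    "DeformedState",
    "InflationSolver",
    "inflate",
    "deflate",
    "cavity_volume",
    "green_strain_fsn",
    "fit_reference_radius",
]

#: radial shape-basis exponents (j, p): G(z) = zbar^j * eps^p with
#: eps = 1 - zbar^2; half-integer powers keep the deformation gradient
#: bounded at the apex
_BASIS_EXPONENTS = ((0, 1.5), (1, 1.5), (0, 2.5), (1, 2.5), (0, 3.5), (1, 3.5))
#: twist-basis powers m: psi(z) = ((z_base - z)/c_endo)^m, vanishing at the
#: prescribed base plane (slice-wise rigid rotation = ventricular torsion)
_TWIST_EXPONENTS = (1, 2)
N_RADIAL = len(_BASIS_EXPONENTS)
N_TWIST = len(_TWIST_EXPONENTS)
N_DOF = N_RADIAL + N_TWIST

# exponent cap inside vectorized energy evaluations; residuals beyond this are
# only used while homing in and keep their (huge, positive) sign
_Q_CAP = 500.0

_MM3_PER_ML = 1000.0


def _shape_functions(z: np.ndarray, c_endo: float):
    """Ansatz basis G_m(z) and derivatives G_m'(z), shapes (n, N_DOF).

    G = zbar^j eps^p; dG/dz = (j zbar^(j-1) eps^p - 2 p zbar^(j+1)
    eps^(p-1)) / c_endo, regular at the apex since p - 1 >= 1/2.
    """
    zbar = z / c_endo
    eps = np.maximum(1.0 - zbar**2, 0.0)
    cols, dcols = [], []
    for j, p in _BASIS_EXPONENTS:
        zj = zbar**j if j else np.ones_like(zbar)
        cols.append(zj * eps**p)
        d = -2.0 * p * zbar * zj * eps ** (p - 1.0)
        if j:
            d = d + eps**p  # j = 1 only
        dcols.append(d / c_endo)
    return np.stack(cols, axis=1), np.stack(dcols, axis=1)


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.mod(a + np.pi, 2.0 * np.pi) - np.pi


def _twist_functions(z: np.ndarray, z_base: float, c_endo: float):
    """Twist basis psi_m(z) (radians per unit DOF) and derivatives."""
    s = (z_base - z) / c_endo
    cols = [s**m for m in _TWIST_EXPONENTS]
    dcols = [-m * s ** (m - 1) / c_endo for m in _TWIST_EXPONENTS]
    return np.stack(cols, axis=1), np.stack(dcols, axis=1)


@dataclass(frozen=True)
class UnloadedGeometry:
    """Unloaded (zero pressure, zero active tension) reference wall.

    Parameters
    ----------
    endo_radius : float
        Equatorial endocardial (short-axis) radius, mm.
    wall_thickness : float
        Radial wall thickness, mm (added to both semi-axes).
    length : float
        Base-to-apex endocardial length, mm; with the truncation fraction
        ``f`` this fixes the endocardial long semi-axis ``c = L/(1+f)`` and
        the base plane ``z_base = f*c``.
    truncation : float
        Base truncation fraction in (0, 1).
    helix_endo_deg, helix_epi_deg : float
        Fiber helix angle at endo- and epicardium, degrees.
    """

    endo_radius: float = 20.0
    wall_thickness: float = 10.0
    length: float = 60.0
    truncation: float = 0.5
    helix_endo_deg: float = 60.0
    helix_epi_deg: float = -60.0

    def __post_init__(self):
        for name in ("endo_radius", "wall_thickness", "length"):
            if not (getattr(self, name) > 0):
                raise ValidationError(f"{name} must be positive")
        if not (0.0 < self.truncation < 1.0):
            raise ValidationError("truncation fraction must lie in (0, 1)")
        if abs(self.helix_endo_deg) < abs(self.helix_epi_deg) - 1e-12:
            raise ValidationError(
                "endocardial helix angle magnitude must be >= epicardial"
            )

    # -- derived scalars ---------------------------------------------------
    @property
    def c_endo(self) -> float:
        """Endocardial long semi-axis, mm."""
        return self.length / (1.0 + self.truncation)

    @property
    def z_base(self) -> float:
        """Axial position of the base plane, mm."""
        return self.truncation * self.c_endo

    def a_of(self, lam):
        return self.endo_radius + lam * self.wall_thickness

    def c_of(self, lam):
        return self.c_endo + lam * self.wall_thickness

    def helix_of(self, lam):
        """Helix angle (radians), linear in the transmural coordinate."""
        deg = self.helix_endo_deg + lam * (self.helix_epi_deg - self.helix_endo_deg)
        return np.deg2rad(deg)

    def shell_volume(self, lam) -> float:
        """Volume (mm^3) enclosed by shell ``lam`` up to the base plane."""
        a, c, zb = self.a_of(lam), self.c_of(lam), self.z_base
        return math.pi * a**2 * (zb - zb**3 / (3.0 * c**2) + 2.0 * c / 3.0)

    @property
    def cavity_volume_ml(self) -> float:
        return self.shell_volume(0.0) / _MM3_PER_ML

    @property
    def wall_volume_ml(self) -> float:
        return (self.shell_volume(1.0) - self.shell_volume(0.0)) / _MM3_PER_ML

    def _basis_integrals(self, n_quad: int = 128) -> np.ndarray:
        """integral of G_m(z) dz over [-c_endo, z_base], fixed quadrature."""
        c, zb = self.c_endo, self.z_base
        x, w = np.polynomial.legendre.leggauss(n_quad)
        z = 0.5 * (zb + c) * x + 0.5 * (zb - c)
        wz = 0.5 * (zb + c) * w
        G, _ = _shape_functions(z, c)
        return G.T @ wz

    def deformed_cavity_volume_ml(self, q: np.ndarray) -> float:
        """Closed-form cavity volume (ml): exactly linear in the DOFs."""
        extra = math.pi * float(
            np.dot(self._basis_integrals(), np.asarray(q)[:N_RADIAL])
        )
        return self.cavity_volume_ml + extra / _MM3_PER_ML

    def material_points(
        self,
        n_transmural: int = 5,
        n_longitudinal: int = 5,
        n_circumferential: int = 8,
    ) -> "MaterialPointSet":
        """Tensor-product quadrature point set over the wall.

        Gauss-Legendre in the transmural and longitudinal material
        coordinates, equally spaced midpoints circumferentially (the optimal
        rule on the circle). Weights are normalized so they sum exactly to
        the reference wall volume.
        """
        xl, wl = np.polynomial.legendre.leggauss(n_transmural)
        xm, wm = np.polynomial.legendre.leggauss(n_longitudinal)
        lam_1d = 0.5 * (xl + 1.0)
        wlam = 0.5 * wl
        mu_1d = 0.5 * (xm + 1.0)
        wmu = 0.5 * wm
        theta_1d = (np.arange(n_circumferential) + 0.5) * (
            2.0 * np.pi / n_circumferential
        )
        wth = np.full(n_circumferential, 2.0 * np.pi / n_circumferential)

        lam, mu, theta = [
            x.ravel() for x in np.meshgrid(lam_1d, mu_1d, theta_1d, indexing="ij")
        ]
        w3 = (wlam[:, None, None] * wmu[None, :, None] * wth[None, None, :]).ravel()

        a = self.a_of(lam)
        c = self.c_of(lam)
        zb = self.z_base
        z = (1.0 - mu) * zb - mu * c
        one = 1.0 - z**2 / c**2
        # volume element: 1/2 d(rho^2)/dlam * (z_base + c(lam)) dlam dmu dtheta
        h = self.wall_thickness
        drho2_dlam = 2.0 * h * (a * one + a**2 * z**2 / c**3)
        jac = 0.5 * drho2_dlam * (zb + c)
        w = w3 * jac
        w *= (self.wall_volume_ml * _MM3_PER_ML) / w.sum()

        rho = a * np.sqrt(np.maximum(one, 0.0))
        pos = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
        return MaterialPointSet(
            lam=lam,
            mu=mu,
            theta=theta,
            weights=w,
            fiber_angle=self.helix_of(lam),
            positions=pos,
            template=self,
        )


@dataclass(frozen=True)
class MaterialPointSet:
    """Gauss-point sample of the wall: material coordinates, quadrature
    weights (mm^3, summing to the reference wall volume), per-point fiber
    helix angle (radians) and current Cartesian positions (mm)."""

    lam: np.ndarray
    mu: np.ndarray
    theta: np.ndarray
    weights: np.ndarray
    fiber_angle: np.ndarray
    positions: np.ndarray
    template: UnloadedGeometry | None = None

    def __post_init__(self):
        n = len(self.lam)
        for name in ("mu", "theta", "weights", "fiber_angle"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length mismatch")
        if self.positions.shape != (n, 3):
            raise ValidationError("positions must be (n, 3)")
        if np.any(self.weights <= 0):
            raise ValidationError("quadrature weights must be positive")

    def __len__(self) -> int:
        return len(self.lam)


@dataclass(frozen=True)
class LoadState:
    """Cavity pressure (kPa) and active tension parameter t_z (kPa)."""

    p: float = 0.0
    t_z: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.p) and math.isfinite(self.t_z)):
            raise ValidationError("load must be finite")


@dataclass(frozen=True)
class BoundaryConditions:
    """Prescribed axial base-plane position (mm) and on-axis apex constraint.

    The ansatz satisfies both by construction; the prescribed base position
    is validated against the reference geometry.
    """

    base_z: float | None = None
    apex_on_axis: bool = True

    def validate_for(self, geom: UnloadedGeometry):
        if self.base_z is not None and abs(self.base_z - geom.z_base) > 1e-6 * max(
            1.0, geom.z_base
        ):
            raise ValidationError(
                f"prescribed base plane z={self.base_z} mm inconsistent with "
                f"reference geometry base z={geom.z_base:.6g} mm"
            )
        if not self.apex_on_axis:
            raise ValidationError("the axisymmetric ansatz keeps the apex on axis")


@dataclass(frozen=True)
class DeformedState:
    """Equilibrium configuration returned by :func:`inflate`."""

    points: MaterialPointSet
    geometry: UnloadedGeometry
    q: np.ndarray  # shape DOFs: radial (mm^2) then twist (rad)
    load: LoadState
    cavity_volume_ml: float
    residual: float  # relative virtual-work residual
    green_strain_fsn: np.ndarray  # (n, 3, 3) per Gauss point

    @property
    def dof(self) -> float:
        """Deformed equatorial endocardial radius (mm), a scalar summary of
        the shape DOFs (the basis evaluated at the equator)."""
        g0, _ = _shape_functions(np.zeros(1), self.geometry.c_endo)
        return math.sqrt(
            self.geometry.endo_radius**2 + float(g0[0] @ self.q[:N_RADIAL])
        )


# ---------------------------------------------------------------------------
# kinematics


class _Kinematics:
    """Precomputed per-point reference data for a geometry + point set.

    The reference is either the parametric family shape or, with
    ``reference_positions``, an observed point cloud (the ansatz keeps the
    axial coordinate material, so a model-reachable cloud is a valid
    reference); triads, weights and basis always come from the scaffold
    geometry.
    """

    def __init__(
        self,
        geom: UnloadedGeometry,
        pts: MaterialPointSet,
        reference_positions: np.ndarray | None = None,
    ):
        self.geom = geom
        self.pts = pts
        lam, mu, theta = pts.lam, pts.mu, pts.theta
        a = geom.a_of(lam)
        c = geom.c_of(lam)
        z = (1.0 - mu) * geom.z_base - mu * c
        one = np.maximum(1.0 - z**2 / c**2, 0.0)
        rho = a * np.sqrt(one)
        self.z = z
        if reference_positions is not None:
            ref = np.asarray(reference_positions, dtype=float)
            self.rho2 = ref[:, 0] ** 2 + ref[:, 1] ** 2
            if np.any(self.rho2 <= 0):
                raise ValidationError("cloud reference radii must be positive")
            self.rho = np.sqrt(self.rho2)
            self.theta_ref = np.arctan2(ref[:, 1], ref[:, 0])
        else:
            self.rho = rho
            self.rho2 = rho**2
            self.theta_ref = np.asarray(theta, dtype=float)
        self.G, self.dG = _shape_functions(z, geom.c_endo)
        self.Psi, self.dPsi = _twist_functions(z, geom.z_base, geom.c_endo)
        self.w = pts.weights

        # local fiber/sheet/normal triad in the cylindrical (rho, theta, z)
        # basis; meridional slope m = d rho / d z on the shell
        with np.errstate(divide="ignore"):
            m = np.where(rho > 0, -(a**2) * z / (c**2 * np.maximum(rho, 1e-300)), 0.0)
        norm = np.sqrt(1.0 + m**2)
        t_m = np.stack([m / norm, np.zeros_like(m), 1.0 / norm], axis=1)  # meridional
        n_t = np.stack([1.0 / norm, np.zeros_like(m), -m / norm], axis=1)  # transmural
        e_t = np.tile(np.array([0.0, 1.0, 0.0]), (len(lam), 1))  # circumferential
        phi = pts.fiber_angle
        f = np.cos(phi)[:, None] * e_t + np.sin(phi)[:, None] * t_m
        s = n_t
        n = np.cross(f, s)
        # rotation with columns f, s, n (cylindrical components)
        self.R = np.stack([f, s, n], axis=2)

    # -- deformation at DOF vector q ---------------------------------------
    # q[:N_RADIAL] are the radial shape DOFs (mm^2), q[N_RADIAL:] the twist
    # DOFs (radians); the twist is a slice-wise rigid rotation, so det F = 1
    # continues to hold exactly.

    def admissible(self, q: np.ndarray) -> bool:
        return bool(np.all(self.rho2 + self.G @ q[:N_RADIAL] > 0.0))

    def _radial(self, q: np.ndarray):
        u2 = self.rho2 + self.G @ q[:N_RADIAL]
        if np.any(u2 <= 0):
            raise UnphysicalStrainError(f"ansatz radius collapses at q={q}")
        return np.sqrt(u2)

    def strain_and_variation(self, q: np.ndarray):
        """Green strain E (n,3,3) and dE/dq_m (n,3,3,N_DOF) in the f/s/n
        frame. Cylindrical components: 0 = radial, 1 = circumferential,
        2 = axial; F has entries rho/u, u/rho, 1 on the diagonal, the
        transmural-axial shear g'/(2u) and the torsional shear u psi'."""
        qr = q[:N_RADIAL]
        qt = q[N_RADIAL:]
        u = self._radial(q)
        rho = self.rho
        gp = self.dG @ qr
        psip = self.dPsi @ qt
        frr = rho / u
        ftt = u / rho
        k = gp / (2.0 * u)
        tz = u * psip  # F_theta'z

        n_pts = len(rho)
        E = np.zeros((n_pts, 3, 3))
        E[:, 0, 0] = 0.5 * (frr**2 - 1.0)
        E[:, 1, 1] = 0.5 * (ftt**2 - 1.0)
        E[:, 2, 2] = 0.5 * (k**2 + tz**2)
        E[:, 0, 2] = E[:, 2, 0] = 0.5 * frr * k
        E[:, 1, 2] = E[:, 2, 1] = 0.5 * ftt * tz

        # dE/dq from the analytic derivatives of F; du/dq_m = G_m/(2u)
        um = self.G / (2.0 * u[:, None])  # (n, N_RADIAL)
        dfrr = -rho[:, None] * um / u[:, None] ** 2
        dftt = um / rho[:, None]
        dk = self.dG / (2.0 * u[:, None]) - gp[:, None] * um / (2.0 * u[:, None] ** 2)
        dtz_r = psip[:, None] * um  # d(u psi')/dq_radial
        dE = np.zeros((n_pts, 3, 3, N_DOF))
        r_sl = slice(0, N_RADIAL)
        t_sl = slice(N_RADIAL, N_DOF)
        dE[:, 0, 0, r_sl] = frr[:, None] * dfrr
        dE[:, 1, 1, r_sl] = ftt[:, None] * dftt
        dE[:, 2, 2, r_sl] = k[:, None] * dk + tz[:, None] * dtz_r
        dE[:, 0, 2, r_sl] = dE[:, 2, 0, r_sl] = 0.5 * (
            dfrr * k[:, None] + frr[:, None] * dk
        )
        dE[:, 1, 2, r_sl] = dE[:, 2, 1, r_sl] = 0.5 * (
            dftt * tz[:, None] + ftt[:, None] * dtz_r
        )
        # twist DOFs: d(psi')/dt_m = dPsi_m, u unchanged
        dtz_t = u[:, None] * self.dPsi
        dE[:, 2, 2, t_sl] = tz[:, None] * dtz_t
        dE[:, 1, 2, t_sl] = dE[:, 2, 1, t_sl] = 0.5 * ftt[:, None] * dtz_t

        R = self.R
        E_fsn = np.einsum("gki,gkl,glj->gij", R, E, R)
        dE_fsn = np.einsum("gki,gklm,glj->gijm", R, dE, R)
        return E_fsn, dE_fsn

    def strain_only(self, q: np.ndarray) -> np.ndarray:
        E, _ = self.strain_and_variation(q)
        return E

    def deformed_positions(self, q: np.ndarray) -> np.ndarray:
        u = self._radial(q)
        theta = self.theta_ref + self.Psi @ q[N_RADIAL:]
        return np.column_stack([u * np.cos(theta), u * np.sin(theta), self.z])

    def fit_q(self, observed_positions: np.ndarray) -> np.ndarray:
        """Closed-form weighted LS shape DOFs matching observed positions:
        rho'^2 is linear in the radial DOFs, the twist angle linear in the
        twist DOFs."""
        w = self.w
        rho_obs2 = observed_positions[:, 0] ** 2 + observed_positions[:, 1] ** 2
        A = self.G.T @ (w[:, None] * self.G)
        b = self.G.T @ (w * (rho_obs2 - self.rho2))
        qr = np.linalg.lstsq(A, b, rcond=None)[0]

        dtheta = _wrap_angle(
            np.arctan2(observed_positions[:, 1], observed_positions[:, 0])
            - self.theta_ref
        )
        At = self.Psi.T @ (w[:, None] * self.Psi)
        bt = self.Psi.T @ (w * dtheta)
        qt = np.linalg.lstsq(At, bt, rcond=None)[0]
        return np.concatenate([qr, qt])


def _vec_passive_stress(E: np.ndarray, g: GuccioneParams, cap: bool = True):
    """Vectorized dW/dE over (n, 3, 3) strains; returns (S, Q)."""
    q = (
        g.c2 * E[:, 0, 0] ** 2
        + g.c3 * (E[:, 1, 1] ** 2 + E[:, 2, 2] ** 2 + 2.0 * E[:, 1, 2] ** 2)
        + g.c4 * (2.0 * E[:, 0, 1] ** 2 + 2.0 * E[:, 0, 2] ** 2)
    )
    eq = np.exp(np.minimum(q, _Q_CAP) if cap else q)
    coef = np.empty_like(E)
    coef[:, 0, 0] = g.c2 * E[:, 0, 0]
    coef[:, 1, 1] = g.c3 * E[:, 1, 1]
    coef[:, 2, 2] = g.c3 * E[:, 2, 2]
    coef[:, 1, 2] = coef[:, 2, 1] = g.c3 * E[:, 1, 2]
    coef[:, 0, 1] = coef[:, 1, 0] = g.c4 * E[:, 0, 1]
    coef[:, 0, 2] = coef[:, 2, 0] = g.c4 * E[:, 0, 2]
    return 2.0 * g.c1 * eq[:, None, None] * coef, q


class InflationSolver:
    """Equilibrium solver for one geometry + material point set.

    Reusable across constitutive parameters and loads (the estimator sweeps
    call it thousands of times). Deterministic: identical inputs (including
    warm starts) give identical outputs.
    """

    #: maximum pressure increment per load step, kPa
    pressure_step = 0.25
    #: maximum active tension increment per load step, kPa
    tension_step = 1.0
    #: relative virtual-work tolerance at the returned state
    rtol = 1e-8
    #: Newton iteration cap per load step
    max_newton = 60
    #: cap on the number of load steps (loads beyond this are rejected as
    #: outside the solver's bracketing range)
    max_load_steps = 200

    def __init__(
        self,
        geom: UnloadedGeometry,
        pts: MaterialPointSet | None = None,
        reference_positions: np.ndarray | None = None,
    ):
        self.geom = geom
        self.pts = pts if pts is not None else geom.material_points()
        self.kin = _Kinematics(geom, self.pts, reference_positions=reference_positions)
        # dV_cav/dq_m, constant; twist is volume neutral
        self.dv_dq = np.concatenate(
            [math.pi * geom._basis_integrals(), np.zeros(N_TWIST)]
        )

    def _work_terms(self, q, g, load, beta, cap=True):
        E, dE = self.kin.strain_and_variation(q)
        S, qexp = _vec_passive_stress(E, g, cap=cap)
        ext_sq = 2.0 * E[:, 0, 0] + 1.0
        if np.any(ext_sq <= 0.0):
            raise UnphysicalStrainError("fiber extension ratio collapsed")
        ta = load.t_z * (1.0 + beta * (np.sqrt(ext_sq) - 1.0))
        per_point = np.einsum("gij,gijm->gm", S, dE) + ta[:, None] * dE[:, 0, 0, :]
        internal = self.kin.w @ per_point  # (3,)
        external = load.p * self.dv_dq
        scale = max(
            float(np.max(np.abs(per_point).T @ self.kin.w)),
            float(np.max(np.abs(external))),
            1e-300,
        )
        return internal - external, scale, E, qexp

    def residual(
        self, q: np.ndarray, g: GuccioneParams, load: LoadState, beta: float
    ) -> np.ndarray:
        """Virtual-work residual vector (kPa mm^3 per mm^2 of DOF)."""
        r, _, _, _ = self._work_terms(np.asarray(q, dtype=float), g, load, beta)
        return r

    def _newton(self, g, load, beta, q0):
        q = np.asarray(q0, dtype=float).copy()
        if not self.kin.admissible(q):
            raise NonConvergenceError("warm start outside the admissible set")
        r, scale, _, _ = self._work_terms(q, g, load, beta)
        for _ in range(self.max_newton):
            rel = float(np.max(np.abs(r))) / scale
            if rel < self.rtol:
                return q
            # forward-difference Jacobian in the three DOFs
            J = np.empty((N_DOF, N_DOF))
            h = 1e-6 * (1.0 + np.abs(q))
            for m in range(N_DOF):
                qp = q.copy()
                qp[m] += h[m]
                if not self.kin.admissible(qp):
                    qp[m] = q[m] - h[m]
                rp, _, _, _ = self._work_terms(qp, g, load, beta)
                J[:, m] = (rp - r) / (qp[m] - q[m])
            try:
                dq = np.linalg.solve(J, -r)
            except np.linalg.LinAlgError:
                raise NonConvergenceError("singular Newton system") from None
            # damped backtracking on the (scaled) residual norm
            t = 1.0
            rn0 = float(np.linalg.norm(r / scale))
            for _ in range(40):
                q_try = q + t * dq
                if self.kin.admissible(q_try):
                    r_try, scale_try, _, _ = self._work_terms(q_try, g, load, beta)
                    if (
                        float(np.linalg.norm(r_try / scale_try))
                        < (1.0 - 1e-4 * t) * rn0
                        or t < 1e-6
                    ):
                        q, r, scale = q_try, r_try, scale_try
                        break
                t *= 0.5
            else:
                raise NonConvergenceError(
                    "line search failed", last_residual=rn0 / scale
                )
        raise NonConvergenceError(
            "Newton iteration cap reached",
            last_residual=float(np.max(np.abs(r))) / scale,
        )

    def solve(
        self,
        g: GuccioneParams,
        load: LoadState,
        beta: float = ActiveTensionModel().beta,
        warm_start: np.ndarray | None = None,
    ) -> DeformedState:
        geom = self.geom
        if load.p == 0.0 and load.t_z == 0.0:
            q = np.zeros(N_DOF)
            return self._state(q, load, self.kin.strain_only(q), 0.0)

        q = None
        if warm_start is not None:
            # try a direct solve at the target load from the warm start
            try:
                q = self._newton(g, load, beta, warm_start)
            except (NonConvergenceError, UnphysicalStrainError):
                q = None
        if q is None:
            n_steps = max(
                1,
                math.ceil(abs(load.p) / self.pressure_step),
                math.ceil(abs(load.t_z) / self.tension_step),
            )
            if n_steps > self.max_load_steps:
                raise NonConvergenceError(
                    f"load (P={load.p} kPa, Tz={load.t_z} kPa) needs {n_steps} "
                    f"steps, above the cap {self.max_load_steps}"
                )
            q = np.zeros(N_DOF)
            for i in range(1, n_steps + 1):
                frac = i / n_steps
                step_load = LoadState(p=frac * load.p, t_z=frac * load.t_z)
                q = self._newton(g, step_load, beta, q)

        r, scale, E, qexp = self._work_terms(q, g, load, beta, cap=False)
        if np.any(qexp > _Q_CAP):
            raise UnphysicalStrainError("strain energy overflow at equilibrium")
        rel = float(np.max(np.abs(r))) / scale
        if rel > self.rtol:
            raise NonConvergenceError(
                f"equilibrium residual {rel:.3g} above tolerance {self.rtol:g}",
                last_residual=rel,
            )
        return self._state(q, load, E, rel)

    def _state(self, q, load, E_fsn, rel) -> DeformedState:
        pts = replace(self.pts, positions=self.kin.deformed_positions(q))
        return DeformedState(
            points=pts,
            geometry=self.geom,
            q=q,
            load=load,
            cavity_volume_ml=self.geom.cavity_volume_ml
            + float(self.dv_dq @ q) / _MM3_PER_ML,
            residual=rel,
            green_strain_fsn=E_fsn,
        )

    def fit_dof(self, observed_positions: np.ndarray) -> float:
        """Equatorial endocardial radius (mm) of the best-fitting ansatz
        member for an observed point cloud."""
        q = self.kin.fit_q(observed_positions)
        g0, _ = _shape_functions(np.zeros(1), self.geom.c_endo)
        s2 = self.geom.endo_radius**2 + float(g0[0] @ q[:N_RADIAL])
        if s2 <= 0:
            raise UnphysicalStrainError("observation implies collapsed endocardium")
        return math.sqrt(s2)


# ---------------------------------------------------------------------------
# public operator surface


def inflate(
    x0: UnloadedGeometry,
    g: GuccioneParams,
    load: LoadState,
    bc: BoundaryConditions | None = None,
    *,
    points: MaterialPointSet | None = None,
    beta: float = ActiveTensionModel().beta,
    warm_start: np.ndarray | None = None,
) -> DeformedState:
    """Forward operator: equilibrium deformed state at the given load."""
    if bc is not None:
        bc.validate_for(x0)
    solver = InflationSolver(x0, points)
    return solver.solve(g, load, beta=beta, warm_start=warm_start)


def deflate(
    y: DeformedState | MaterialPointSet,
    g: GuccioneParams,
    load: LoadState,
    bc: BoundaryConditions | None = None,
    *,
    template: UnloadedGeometry | None = None,
    beta: float = ActiveTensionModel().beta,
    damping: float = 0.8,
    max_iter: int = 100,
    full_output: bool = False,
):
    """Backward (deflation) operator: recover the unloaded configuration.

    Damped fixed-point iteration on the reference point cloud (update =
    observation - inflate(current state), applied to the squared radii; the
    axial coordinate is material under the ansatz). On convergence the
    inflated reference reproduces the observation point by point. Returns
    the best-fitting member of the parametric reference family (with
    ``full_output``, also the converged reference point positions).
    Non-radius fields (thickness, length, truncation, fiber angles) come
    from ``template`` — in the estimation pipeline these are meshing-stage
    constants, not part of the inverse problem.
    """
    pts = y.points if isinstance(y, DeformedState) else y
    if template is None:
        template = pts.template
    if template is None:
        raise ValidationError("deflate needs a template geometry")
    if bc is not None:
        bc.validate_for(template)

    obs = pts.positions
    rho2_obs = obs[:, 0] ** 2 + obs[:, 1] ** 2
    theta_obs = np.arctan2(obs[:, 1], obs[:, 0])
    scale = float(np.mean(rho2_obs))

    # damped fixed point on the reference point cloud:
    # update = observation - inflate(current), applied to the squared radii
    # and twist angles (the axial coordinate is material under the ansatz)
    rho2_ref = rho2_obs.copy()
    theta_ref = theta_obs.copy()
    scaffold = fit_reference_radius(template, obs, pts)
    z_grid = _Kinematics(scaffold, pts).z
    last = None
    warm = None

    def positions_of(rho2, theta):
        r = np.sqrt(rho2)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), z_grid])

    for _ in range(max_iter):
        ref_positions = positions_of(rho2_ref, theta_ref)
        # keep the scaffold (material triads) consistent with the cloud
        scaffold = fit_reference_radius(template, ref_positions, pts)
        solver = InflationSolver(scaffold, pts, reference_positions=ref_positions)
        state = solver.solve(g, load, beta=beta, warm_start=warm)
        warm = state.q
        sim = state.points.positions
        rho2_sim = sim[:, 0] ** 2 + sim[:, 1] ** 2
        mismatch = rho2_obs - rho2_sim
        dtheta = _wrap_angle(theta_obs - np.arctan2(sim[:, 1], sim[:, 0]))
        last = max(
            float(np.max(np.abs(mismatch))) / scale, float(np.max(np.abs(dtheta)))
        )
        if last < 1e-12:
            break
        rho2_ref = rho2_ref + damping * mismatch
        theta_ref = theta_ref + damping * dtheta
        if np.any(rho2_ref <= 0):
            raise NonConvergenceError(
                "deflation drove reference radii negative", last_residual=last
            )
    else:
        raise NonConvergenceError(
            f"deflation fixed point not converged in {max_iter} iterations",
            last_residual=last,
        )

    ref_positions = positions_of(rho2_ref, theta_ref)
    geom = fit_reference_radius(template, ref_positions, pts)
    if full_output:
        return geom, ref_positions
    return geom


def _point_counts(pts: MaterialPointSet) -> tuple[int, int, int]:
    """Recover the tensor-product counts of a generated point set."""
    n_l = len(np.unique(np.round(pts.lam, 12)))
    n_m = len(np.unique(np.round(pts.mu, 12)))
    n_t = len(np.unique(np.round(pts.theta, 12)))
    if n_l * n_m * n_t != len(pts):
        raise ValidationError("point set is not a tensor-product grid")
    return n_l, n_m, n_t


def cavity_volume(s: DeformedState, n_quad: int = 64) -> float:
    """LV cavity volume (ml): endocardial surface of revolution closed by the
    base plane, integrated with fixed-order Gauss quadrature."""
    geom = s.geometry
    c = geom.c_endo
    zb = geom.z_base
    x, w = np.polynomial.legendre.leggauss(n_quad)
    z = 0.5 * (zb + c) * x + 0.5 * (zb - c)  # map [-1,1] -> [-c, zb]
    wz = 0.5 * (zb + c) * w
    eps = np.maximum(1.0 - z**2 / c**2, 0.0)
    G, _ = _shape_functions(z, c)
    rho2 = geom.endo_radius**2 * eps + G @ np.asarray(s.q)[:N_RADIAL]
    return float(np.pi * np.sum(wz * rho2)) / _MM3_PER_ML


def green_strain_fsn(
    x0: UnloadedGeometry, s: DeformedState, point: int | tuple
) -> GreenStrain:
    """Green strain in the f/s/n frame at one material point.

    ``point`` is either an index into the state's point set or a material
    coordinate triple ``(lam, mu, theta)``.
    """
    if isinstance(point, (int, np.integer)):
        return GreenStrain.from_tensor(s.green_strain_fsn[int(point)])
    lam, mu, theta = point
    pts = MaterialPointSet(
        lam=np.array([lam]),
        mu=np.array([mu]),
        theta=np.array([theta]),
        weights=np.array([1.0]),
        fiber_angle=np.atleast_1d(x0.helix_of(np.array([lam])))[:1],
        positions=np.zeros((1, 3)),
        template=x0,
    )
    kin = _Kinematics(x0, pts)
    return GreenStrain.from_tensor(kin.strain_only(np.asarray(s.q))[0])


def fit_reference_radius(
    template: UnloadedGeometry, positions: np.ndarray, pts: MaterialPointSet
) -> UnloadedGeometry:
    """Approximate a point-cloud observation by a member of the reference
    family: weighted least-squares fit of the endocardial radius with the
    remaining geometry fields held at the template values (the
    "reference state is the observed frame" initialization).

    The reference radius of a material point is linear in the endocardial
    radius, rho = (a + lam*h) * sqrt(1 - z^2/c(lam)^2), so the fit is closed
    form.
    """
    lam, mu = pts.lam, pts.mu
    c = template.c_of(lam)
    z = (1.0 - mu) * template.z_base - mu * c
    root = np.sqrt(np.maximum(1.0 - z**2 / c**2, 0.0))
    rho_obs = np.hypot(positions[:, 0], positions[:, 1])
    w = pts.weights
    h = template.wall_thickness
    denom = float(np.sum(w * root**2))
    if denom <= 0:
        raise ValidationError("degenerate point set for geometry fit")
    a_fit = float(np.sum(w * root * (rho_obs - lam * h * root)) / denom)
    if a_fit <= 0:
        raise ValidationError("fitted endocardial radius is not positive")
    return replace(template, endo_radius=a_fit)
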