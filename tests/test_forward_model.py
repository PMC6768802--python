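"""Reduced-order inflation/deflation operators: kinematic oracles (finite
differences), incompressibility, equilibrium, monotonicity, round trips."""

import math
from dataclasses import replace

import numpy as np
import pytest

from diastolefit.constitutive import GuccioneParams
from diastolefit.exceptions import NonConvergenceError, ValidationError
from diastolefit.forward_model import (
    N_DOF,
    N_RADIAL,
    BoundaryConditions,
    InflationSolver,
    LoadState,
    UnloadedGeometry,
    _Kinematics,
    _shape_functions,
    _twist_functions,
    cavity_volume,
    deflate,
    fit_reference_radius,
    green_strain_fsn,
    inflate,
)


def random_dofs(rng, radial_lo=-10.0, radial_hi=40.0, twist=0.15):
    return np.concatenate(
        [
            rng.uniform(radial_lo, radial_hi, size=N_RADIAL),
            rng.uniform(-twist, twist, size=N_DOF - N_RADIAL),
        ]
    )


@pytest.fixture(scope="module")
def geom():
    return UnloadedGeometry()


@pytest.fixture(scope="module")
def params(healthy_params):
    return healthy_params


class TestGeometry:
    def test_validation(self):
        with pytest.raises(ValidationError):
            UnloadedGeometry(endo_radius=-1)
        with pytest.raises(ValidationError):
            UnloadedGeometry(truncation=1.5)
        with pytest.raises(ValidationError):
            UnloadedGeometry(helix_endo_deg=30, helix_epi_deg=-60)

    def test_quadrature_weights_sum_to_wall_volume(self, geom):
        pts = geom.material_points()
        assert np.all(pts.weights > 0)
        assert pts.weights.sum() == pytest.approx(
            geom.wall_volume_ml * 1000.0, rel=1e-12
        )

    def test_point_count_matches_order(self, geom):
        assert len(geom.material_points(3, 5, 7)) == 3 * 5 * 7

    def test_helix_linear_in_transmural_coordinate(self, geom):
        assert geom.helix_of(0.0) == pytest.approx(np.deg2rad(60))
        assert geom.helix_of(1.0) == pytest.approx(np.deg2rad(-60))
        assert geom.helix_of(0.5) == pytest.approx(0.0)

    def test_boundary_conditions_validation(self, geom):
        BoundaryConditions(base_z=geom.z_base).validate_for(geom)
        with pytest.raises(ValidationError):
            BoundaryConditions(base_z=geom.z_base + 5.0).validate_for(geom)
        with pytest.raises(ValidationError):
            BoundaryConditions(apex_on_axis=False).validate_for(geom)


class TestKinematics:
    def test_identity_at_zero_dof(self, geom):
        pts = geom.material_points()
        kin = _Kinematics(geom, pts)
        E, _ = kin.strain_and_variation(np.zeros(N_DOF))
        assert np.allclose(E, 0.0, atol=1e-14)
        assert np.allclose(kin.deformed_positions(np.zeros(N_DOF)), pts.positions)

    def test_pointwise_incompressibility(self, geom, rng):
        """det F = 1 exactly: the slice-wise radial map conserves area.

        Checked through the principal structure of F: F_rr * F_tt * F_zz = 1
        with the (triangular) shear not entering the determinant; here via
        the invariant det(2E + I) = (det F)^2 = 1.
        """
        kin = _Kinematics(geom, geom.material_points())
        for _ in range(5):
            q = random_dofs(rng, -30, 60)
            if not kin.admissible(q):
                continue
            E, _ = kin.strain_and_variation(q)
            C = 2.0 * E + np.eye(3)
            assert np.allclose(np.linalg.det(C), 1.0, atol=1e-9)

    def test_deformation_gradient_against_finite_difference(self, geom, rng):
        """The analytic strain agrees with strains built from a finite
        difference of the radial map rho' = sqrt(rho^2 + g(z))."""
        pts = geom.material_points(3, 3, 2)
        kin = _Kinematics(geom, pts)
        q = random_dofs(rng)
        E, _ = kin.strain_and_variation(q)
        h = 1e-6
        c_endo, z_base = geom.c_endo, geom.z_base

        def rho_prime(rho, z):
            G, _ = _shape_functions(np.atleast_1d(z), c_endo)
            return np.sqrt(rho**2 + float(G[0] @ q[:N_RADIAL]))

        def twist(z):
            Psi, _ = _twist_functions(np.atleast_1d(z), z_base, c_endo)
            return float(Psi[0] @ q[N_RADIAL:])

        for g_idx in range(0, len(pts), 7):
            rho, z = kin.rho[g_idx], kin.z[g_idx]
            F = np.zeros((3, 3))
            F[0, 0] = (rho_prime(rho + h, z) - rho_prime(rho - h, z)) / (2 * h)
            F[1, 1] = rho_prime(rho, z) / rho
            F[2, 2] = 1.0
            F[0, 2] = (rho_prime(rho, z + h) - rho_prime(rho, z - h)) / (2 * h)
            F[1, 2] = rho_prime(rho, z) * (twist(z + h) - twist(z - h)) / (2 * h)
            E_cyl = 0.5 * (F.T @ F - np.eye(3))
            R = kin.R[g_idx]
            E_fsn = R.T @ E_cyl @ R
            assert np.allclose(E_fsn, E[g_idx], atol=1e-6)

    def test_strain_variation_against_finite_difference(self, geom, rng):
        kin = _Kinematics(geom, geom.material_points(3, 3, 2))
        q = random_dofs(rng, -5, 30)
        E0, dE = kin.strain_and_variation(q)
        h = 1e-6
        for m in range(N_DOF):
            qp, qm = q.copy(), q.copy()
            qp[m] += h
            qm[m] -= h
            fd = (kin.strain_and_variation(qp)[0] - kin.strain_and_variation(qm)[0]) / (
                2 * h
            )
            assert np.allclose(fd, dE[..., m], atol=1e-6)

    def test_triad_orthonormal(self, geom):
        kin = _Kinematics(geom, geom.material_points())
        prod = np.einsum("gki,gkj->gij", kin.R, kin.R)
        assert np.allclose(prod, np.eye(3), atol=1e-12)

    def test_uniform_isotropic_stretch_block(self):
        """Closed form: diagonal entries (lam^2 - 1)/2 in any frame for a
        uniform stretch (checked on the frame-rotation path)."""
        lam = 1.07
        E_cart = 0.5 * (lam**2 - 1.0) * np.eye(3)
        kin = _Kinematics(UnloadedGeometry(), UnloadedGeometry().material_points(2, 2, 2))
        E_fsn = np.einsum("gki,kl,glj->gij", kin.R, E_cart, kin.R)
        assert np.allclose(E_fsn, E_cart[None], atol=1e-12)


class TestInflate:
    def test_unloaded_identity(self, geom, params):
        state = inflate(geom, params, LoadState(0.0, 0.0))
        assert state.residual == 0.0
        assert np.allclose(state.points.positions, geom.material_points().positions)
        assert state.cavity_volume_ml == pytest.approx(geom.cavity_volume_ml)

    def test_passive_inflation_monotone_in_pressure(self, geom, params):
        solver = InflationSolver(geom)
        vols = []
        warm = None
        for p in (0.5, 1.0, 1.5, 2.0):
            st = solver.solve(params, LoadState(p=p), warm_start=warm)
            warm = st.q
            vols.append(st.cavity_volume_ml)
        assert vols[0] > geom.cavity_volume_ml
        assert np.all(np.diff(vols) > 0)

    def test_active_contraction_shrinks_cavity(self, geom, params):
        st = inflate(geom, params, LoadState(p=0.0, t_z=5.0))
        assert st.cavity_volume_ml < geom.cavity_volume_ml

    def test_tension_monotone_at_fixed_pressure(self, geom, params):
        solver = InflationSolver(geom)
        v1 = solver.solve(params, LoadState(p=1.0, t_z=1.0)).cavity_volume_ml
        v2 = solver.solve(params, LoadState(p=1.0, t_z=4.0)).cavity_volume_ml
        assert v2 < v1

    def test_equilibrium_residual_below_tolerance(self, geom, params):
        st = inflate(geom, params, LoadState(p=2.0, t_z=1.0))
        assert st.residual < 1e-8

    def test_returned_dofs_locally_minimize_residual(self, geom, params):
        """Dense 1-D grid search along each DOF axis: the residual magnitude
        is smallest at the returned equilibrium within grid spacing."""
        solver = InflationSolver(geom)
        load = LoadState(p=1.5)
        st = solver.solve(params, load)
        beta = 1.45
        for m in range(N_DOF):
            half = 2.0 if m < N_RADIAL else 0.02
            offsets = np.linspace(-half, half, 41)
            norms = []
            for d in offsets:
                qq = st.q.copy()
                qq[m] += d
                norms.append(abs(solver.residual(qq, params, load, beta)[m]))
            assert abs(offsets[int(np.argmin(norms))]) <= (offsets[1] - offsets[0])

    def test_determinism(self, geom, params):
        a = inflate(geom, params, LoadState(p=1.7, t_z=0.8))
        b = inflate(geom, params, LoadState(p=1.7, t_z=0.8))
        assert np.array_equal(a.q, b.q)
        assert np.array_equal(a.points.positions, b.points.positions)

    def test_isotropic_law_ignores_helix_angle(self, geom):
        """With c2 = c3 = c4 the exponent is frame invariant, so the
        response cannot depend on the fiber helix."""
        iso = GuccioneParams(1.0, 10.0, 10.0, 10.0)
        st1 = inflate(geom, iso, LoadState(p=1.0))
        geom0 = replace(geom, helix_endo_deg=0.0, helix_epi_deg=0.0)
        st2 = inflate(geom0, iso, LoadState(p=1.0))
        assert np.allclose(st1.q, st2.q, atol=1e-6)

    def test_nonconvergence_reported(self, geom, params):
        with pytest.raises(NonConvergenceError):
            inflate(geom, params, LoadState(p=1e5))

    def test_quadrature_convergence(self, geom, params):
        """Doubling the quadrature order changes the cavity volume by < 0.1%."""
        load = LoadState(p=2.0, t_z=0.5)
        v5 = InflationSolver(geom, geom.material_points(5, 5, 8)).solve(params, load)
        v10 = InflationSolver(geom, geom.material_points(10, 10, 8)).solve(params, load)
        assert v10.cavity_volume_ml == pytest.approx(v5.cavity_volume_ml, rel=1e-3)


class TestDeflate:
    def test_zero_load_identity(self, geom, params):
        st = inflate(geom, params, LoadState(0.0, 0.0))
        x0 = deflate(st, params, LoadState(0.0, 0.0))
        assert x0.endo_radius == pytest.approx(geom.endo_radius, abs=1e-9)

    @pytest.mark.parametrize(
        "radius,load",
        [
            (20.0, LoadState(p=2.0)),
            (17.5, LoadState(p=1.0, t_z=2.0)),
            (23.0, LoadState(p=1.3, t_z=-1.0)),
        ],
    )
    def test_roundtrip_recovers_unloaded_state(self, params, radius, load):
        x0 = UnloadedGeometry(endo_radius=radius)
        y = inflate(x0, params, load)
        back = deflate(y, params, load)
        assert back.endo_radius == pytest.approx(radius, abs=1e-6)
        y2 = inflate(back, params, load)
        rms = np.sqrt(((y2.points.positions - y.points.positions) ** 2).sum(1).mean())
        assert rms < 1e-6

    def test_deflation_from_loaded_state_shrinks_cavity(self, geom, params):
        y = inflate(geom, params, LoadState(p=2.0))
        x0 = deflate(y, params, LoadState(p=2.0))
        ref = inflate(x0, params, LoadState(0.0, 0.0))
        assert ref.cavity_volume_ml < y.cavity_volume_ml

    def test_missing_template_rejected(self, geom, params):
        st = inflate(geom, params, LoadState(p=1.0))
        pts = replace(st.points, template=None)
        with pytest.raises(ValidationError):
            deflate(pts, params, LoadState(p=1.0))


class TestCavityVolume:
    def test_near_full_ellipsoid_closed_form(self, params):
        """With the truncation pushed to the top the cavity approaches the
        closed-form ellipsoid volume 4/3 pi a^2 c."""
        g = UnloadedGeometry(endo_radius=20.0, length=79.6, truncation=0.999)
        st = inflate(g, params, LoadState(0.0, 0.0))
        expected = 4.0 / 3.0 * math.pi * 20.0**2 * g.c_endo / 1000.0
        assert cavity_volume(st) == pytest.approx(expected, rel=1e-3)

    def test_scaling_cubes(self, params):
        g1 = UnloadedGeometry(endo_radius=20, wall_thickness=10, length=60)
        g2 = UnloadedGeometry(endo_radius=40, wall_thickness=20, length=120)
        s1 = inflate(g1, params, LoadState(0.0, 0.0))
        s2 = inflate(g2, params, LoadState(0.0, 0.0))
        assert cavity_volume(s2) == pytest.approx(8.0 * cavity_volume(s1), rel=1e-12)

    def test_inflation_increases_quadrature_volume(self, geom, params):
        s0 = inflate(geom, params, LoadState(0.0, 0.0))
        s1 = inflate(geom, params, LoadState(p=1.0))
        assert cavity_volume(s1) > cavity_volume(s0)

    def test_quadrature_matches_closed_form(self, geom, params):
        s = inflate(geom, params, LoadState(p=2.0))
        assert cavity_volume(s) == pytest.approx(s.cavity_volume_ml, rel=1e-8)


class TestGreenStrainAccessor:
    def test_identity_strain_zero(self, geom, params):
        st = inflate(geom, params, LoadState(0.0, 0.0))
        e = green_strain_fsn(geom, st, (0.5, 0.3, 1.0))
        assert np.allclose(e.tensor(), 0.0, atol=1e-14)

    def test_index_and_coordinate_paths_agree(self, geom, params):
        st = inflate(geom, params, LoadState(p=1.5))
        pts = st.points
        i = 17
        by_index = green_strain_fsn(geom, st, i).tensor()
        by_coord = green_strain_fsn(
            geom, st, (pts.lam[i], pts.mu[i], pts.theta[i])
        ).tensor()
        assert np.allclose(by_index, by_coord, atol=1e-12)


class TestReferenceFit:
    def test_recovers_family_member(self, geom):
        pts = geom.material_points()
        target = replace(geom, endo_radius=21.7)
        fitted = fit_reference_radius(geom, target.material_points().positions, pts)
        assert fitted.endo_radius == pytest.approx(21.7, abs=1e-9)
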