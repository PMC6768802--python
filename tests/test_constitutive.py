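"""Constitutive law: reformulation bijection, energy/stress closed forms
against independent oracles (finite differences, sympy), active tension."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diastolefit.constitutive import (
    ActiveTensionModel,
    GreenStrain,
    GuccioneParams,
    ReformulatedParams,
    active_tension,
    exponent_q,
    passive_stress,
    reformulate,
    restore,
    strain_energy,
    total_stress,
)
from diastolefit.exceptions import (
    DegenerateParameterError,
    UnphysicalStrainError,
    ValidationError,
)

finite_pos = st.floats(min_value=0.01, max_value=100.0, allow_nan=False)
finite_nonneg = st.floats(min_value=0.0, max_value=100.0, allow_nan=False)


def small_strain(rng, scale=0.15):
    comps = rng.uniform(-scale, scale, size=6)
    return GreenStrain(*comps)


class TestReformulation:
    def test_symmetric_example(self):
        r = reformulate(GuccioneParams(1, 1, 1, 1))
        assert r.alpha == 3
        for frac in (r.r2, r.r3, r.r4):
            assert frac == pytest.approx(1 / 3, rel=1e-12)

    def test_healthy_magnitudes(self, healthy_params):
        r = reformulate(healthy_params)
        assert r.alpha == pytest.approx(42.56)
        assert r.r3 == pytest.approx(0.25070, abs=1e-5)
        assert r.r4 == pytest.approx(0.29981, abs=1e-5)

    def test_restore_example(self):
        g = restore(
            ReformulatedParams(
                c1=1, alpha=42.56, r2=1 - 0.25070 - 0.29981, r3=0.25070, r4=0.29981
            )
        )
        assert g.c2 == pytest.approx(19.13, abs=1e-3)
        assert g.c3 == pytest.approx(10.67, abs=1e-3)
        assert g.c4 == pytest.approx(12.76, abs=1e-3)

    @given(
        c1=finite_pos,
        c2=finite_nonneg,
        c3=finite_nonneg,
        c4=finite_nonneg,
    )
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip_bijection(self, c1, c2, c3, c4):
        if c2 + c3 + c4 <= 0:
            return
        g = GuccioneParams(c1, c2, c3, c4)
        back = restore(reformulate(g))
        for name in ("c1", "c2", "c3", "c4"):
            assert getattr(back, name) == pytest.approx(
                getattr(g, name), rel=1e-12, abs=1e-12
            )

    def test_degenerate_alpha(self):
        with pytest.raises(DegenerateParameterError):
            GuccioneParams(1.0, 0.0, 0.0, 0.0)
        with pytest.raises(DegenerateParameterError):
            ReformulatedParams(c1=1.0, alpha=0.0, r2=1 / 3, r3=1 / 3, r4=1 / 3)

    def test_fraction_sum_invariant(self):
        with pytest.raises(ValidationError):
            ReformulatedParams(c1=1.0, alpha=1.0, r2=0.5, r3=0.5, r4=0.5)


class TestExponentAndEnergy:
    def test_zero_strain(self, healthy_params):
        e = GreenStrain()
        assert exponent_q(e, healthy_params) == 0.0
        assert strain_energy(e, healthy_params) == 0.0

    def test_fiber_only_hand_value(self, healthy_params):
        e = GreenStrain(e_ff=0.1)
        assert exponent_q(e, healthy_params) == pytest.approx(0.1913)
        assert strain_energy(e, healthy_params) == pytest.approx(
            math.exp(0.1913) - 1.0, rel=1e-12
        )

    def test_quadratic_homogeneity(self, healthy_params, rng):
        e = small_strain(rng)
        doubled = GreenStrain(*(2 * np.array([e.e_ff, e.e_ss, e.e_nn, e.e_sn, e.e_fn, e.e_fs])))
        assert exponent_q(doubled, healthy_params) == pytest.approx(
            4.0 * exponent_q(e, healthy_params), rel=1e-12
        )

    def test_shear_sign_invariance(self, healthy_params, rng):
        e = small_strain(rng)
        flipped = GreenStrain(e.e_ff, e.e_ss, e.e_nn, -e.e_sn, -e.e_fn, -e.e_fs)
        assert exponent_q(flipped, healthy_params) == exponent_q(e, healthy_params)

    def test_energy_monotone_in_each_component(self, healthy_params):
        base = strain_energy(GreenStrain(e_ff=0.05), healthy_params)
        assert strain_energy(GreenStrain(e_ff=0.10), healthy_params) > base
        assert strain_energy(GreenStrain(e_ff=0.05, e_sn=0.05), healthy_params) > base

    def test_overflow_reported(self, healthy_params):
        with pytest.raises(UnphysicalStrainError):
            strain_energy(GreenStrain(e_ff=10.0), healthy_params)


class TestPassiveStress:
    def test_zero_at_zero(self, healthy_params):
        assert np.allclose(passive_stress(GreenStrain(), healthy_params).tensor, 0.0)

    def test_fiber_component_hand_value(self, healthy_params):
        s = passive_stress(GreenStrain(e_ff=0.1), healthy_params)
        assert s.tensor[0, 0] == pytest.approx(
            2 * 19.13 * 0.1 * math.exp(0.1913), rel=1e-12
        )

    def test_matches_finite_difference(self, healthy_params, rng):
        """dW/dE against the central difference of the energy, treating E as
        a symmetric tensor (off-diagonal perturbations hit both slots)."""
        h = 1e-6
        for _ in range(10):
            e = small_strain(rng)
            s = passive_stress(e, healthy_params).tensor
            et = e.tensor()
            for i in range(3):
                for j in range(3):
                    de = np.zeros((3, 3))
                    de[i, j] = de[j, i] = h
                    wp = strain_energy(GreenStrain.from_tensor(et + de), healthy_params)
                    wm = strain_energy(GreenStrain.from_tensor(et - de), healthy_params)
                    fd = (wp - wm) / (2 * h)
                    expected = s[i, j] if i == j else 2.0 * s[i, j]
                    assert fd == pytest.approx(expected, rel=1e-6, abs=1e-8)

    def test_matches_sympy_gradient(self, healthy_params):
        """Independent symbolic derivation of dW/dE."""
        sympy = pytest.importorskip("sympy")
        comps = sympy.symbols("eff ess enn esn efn efs")
        eff, ess, enn, esn, efn, efs = comps
        g = healthy_params
        q = (
            g.c2 * eff**2
            + g.c3 * (ess**2 + enn**2 + 2 * esn**2)
            + g.c4 * (2 * efs**2 + 2 * efn**2)
        )
        w = g.c1 * (sympy.exp(q) - 1)
        point = {c: v for c, v in zip(comps, (0.08, -0.03, 0.05, 0.02, -0.04, 0.06))}
        e = GreenStrain(*[point[c] for c in comps])
        s = passive_stress(e, g).tensor
        # tensor derivative: diagonal = dW/dcomp, off-diagonal = dW/dcomp / 2
        assert float(sympy.diff(w, eff).subs(point)) == pytest.approx(s[0, 0], rel=1e-12)
        assert float(sympy.diff(w, ess).subs(point)) == pytest.approx(s[1, 1], rel=1e-12)
        assert float(sympy.diff(w, enn).subs(point)) == pytest.approx(s[2, 2], rel=1e-12)
        assert float(sympy.diff(w, esn).subs(point)) / 2 == pytest.approx(s[1, 2], rel=1e-12)
        assert float(sympy.diff(w, efn).subs(point)) / 2 == pytest.approx(s[0, 2], rel=1e-12)
        assert float(sympy.diff(w, efs).subs(point)) / 2 == pytest.approx(s[0, 1], rel=1e-12)


class TestActiveTension:
    def test_unit_extension(self):
        at = ActiveTensionModel(t_z=5.0, beta=1.45)
        assert active_tension(at, 0.0) == pytest.approx(5.0)

    def test_length_dependence_hand_value(self):
        at = ActiveTensionModel(t_z=8.0, beta=1.45)
        assert active_tension(at, 0.105) == pytest.approx(9.16, rel=1e-12)

    def test_zero_tension(self):
        at = ActiveTensionModel(t_z=0.0)
        for e_ff in (-0.2, 0.0, 0.3):
            assert active_tension(at, e_ff) == 0.0

    def test_unphysical_extension(self):
        with pytest.raises(UnphysicalStrainError):
            active_tension(ActiveTensionModel(t_z=1.0), -0.6)


class TestTotalStress:
    def test_zero_everything(self, healthy_params):
        t = total_stress(GreenStrain(), 0.0, healthy_params, ActiveTensionModel())
        assert np.allclose(t.tensor, 0.0)

    def test_pure_hydrostatic(self, healthy_params):
        t = total_stress(GreenStrain(), 2.0, healthy_params, ActiveTensionModel())
        assert np.allclose(t.tensor, 2.0 * np.eye(3))

    def test_decomposition(self, healthy_params, rng):
        """total - passive - hydrostatic leaves only the fiber-fiber slot,
        equal to the length-dependent active tension."""
        at = ActiveTensionModel(t_z=3.0, beta=1.45)
        for _ in range(5):
            e = small_strain(rng, scale=0.1)
            p = rng.uniform(-2, 2)
            tot = total_stress(e, p, healthy_params, at).tensor
            rest = (
                tot
                - passive_stress(e, healthy_params).tensor
                - p * np.linalg.inv(e.right_cauchy_green())
            )
            expected = np.zeros((3, 3))
            expected[0, 0] = active_tension(at, e.e_ff)
            assert np.allclose(rest, expected, atol=1e-10)

    def test_zero_tz_reduces_to_passive(self, healthy_params, rng):
        e = small_strain(rng, scale=0.1)
        tot = total_stress(e, 0.0, healthy_params, ActiveTensionModel(t_z=0.0)).tensor
        pas = passive_stress(e, healthy_params).tensor
        assert np.allclose(tot, pas, atol=1e-12)

    def test_singular_right_cauchy_green(self, healthy_params):
        with pytest.raises(UnphysicalStrainError):
            total_stress(
                GreenStrain(e_ff=-0.5), 1.0, healthy_params, ActiveTensionModel()
            )
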