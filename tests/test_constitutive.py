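"""Constitutive laws: curve shapes, energy densities, stress consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from myofem import (
    FibreForceLengthCurves,
    TissueMaterial,
    YeohCoefficients,
    base_energy_density,
    eval_fibre_stress,
    fibre_energy_density,
    pk2_stress_components,
    volumetric_energy_density,
)
from myofem.constitutive import (
    APONEUROSIS_BASE_CONTROL_POINTS,
    MUSCLE_BASE_CONTROL_POINTS,
    ElementInversionError,
    fit_yeoh_uniaxial,
)


def _random_F(rng, scale=0.15):
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.4:
            return F


def _unit(rng):
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


class TestFibreCurves:
    def test_active_peak_is_one_at_optimal_length(self):
        c = FibreForceLengthCurves.muscle()
        assert float(c.active_curve(1.0)) == 1.0

    @settings(derandomize=True, max_examples=200)
    @given(lam=st.floats(0.05, 3.0))
    def test_active_bounded_and_zero_outside_support(self, lam):
        c = FibreForceLengthCurves.muscle()
        f = float(c.active_curve(lam))
        assert 0.0 <= f <= 1.0
        lo, hi = c.active_support
        if lam < lo or lam > hi:
            assert f == 0.0

    @settings(derandomize=True, max_examples=200)
    @given(lam=st.floats(0.05, 3.0), dlam=st.floats(0.0, 0.5))
    def test_passive_zero_in_compression_and_nondecreasing(self, lam, dlam):
        c = FibreForceLengthCurves.muscle()
        if lam <= 1.0:
            assert float(c.passive_curve(lam)) == 0.0
        assert float(c.passive_curve(lam + dlam)) >= float(c.passive_curve(lam))

    @pytest.mark.parametrize("which", ["muscle", "aponeurosis"])
    def test_curves_continuous_and_passive_c1_at_joins(self, which):
        c = getattr(FibreForceLengthCurves, which)()
        lams = np.linspace(0.3, 2.0, 20001)
        for curve in (c.active_curve, c.passive_curve):
            vals = np.asarray(curve(lams), dtype=float)
            # a jump would be O(curve scale); finite slopes give O(scale * h)
            assert np.max(np.abs(np.diff(vals))) < 5e-3 * max(1.0, vals.max())
        dp = np.gradient(np.asarray(c.passive_curve(lams), dtype=float), lams)
        assert np.max(np.abs(np.diff(dp))) < 5e-2 * max(dp.max(), 1.0)  # C1

    def test_aponeurosis_has_no_active_response(self):
        c = FibreForceLengthCurves.aponeurosis()
        assert np.all(np.asarray(c.active_curve(np.linspace(0.5, 1.6, 50))) == 0.0)


class TestFibreStress:
    def test_full_activation_at_optimal_length_gives_sigma_max(self, muscle):
        assert float(eval_fibre_stress(1.0, 1.0, muscle)) == pytest.approx(200e3)

    def test_passive_only_is_zero_at_or_below_optimal(self, muscle):
        assert float(eval_fibre_stress(1.0, 0.0, muscle)) == 0.0
        assert float(eval_fibre_stress(0.9, 0.0, muscle)) == 0.0

    def test_matches_independent_curve_evaluation(self, muscle):
        lam, a = 1.3, 0.5
        expected = 200e3 * (a * float(muscle.fibre_curves.active_curve(lam))
                            + float(muscle.fibre_curves.passive_curve(lam)))
        assert float(eval_fibre_stress(lam, a, muscle)) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_invalid_stretch_rejected(self, muscle, bad):
        with pytest.raises(ValueError):
            eval_fibre_stress(bad, 0.5, muscle)

    def test_out_of_range_activation_rejected(self, muscle):
        with pytest.raises(ValueError):
            eval_fibre_stress(1.0, 1.5, muscle)


class TestEnergyDensities:
    def test_fibre_energies_vanish_at_reference(self, muscle):
        psi_a, psi_p = fibre_energy_density(1.0, 0.7, muscle)
        assert float(psi_a) == 0.0 and float(psi_p) == 0.0

    def test_active_energy_negative_under_shortening(self, muscle):
        psi_a, _ = fibre_energy_density(0.86, 1.0, muscle)
        assert float(psi_a) < 0.0

    @pytest.mark.parametrize("lam", [0.7, 0.86, 1.2, 1.5])
    def test_integrals_match_adaptive_quadrature(self, muscle, lam):
        c = muscle.fibre_curves
        psi_a, psi_p = fibre_energy_density(lam, 1.0, muscle)
        brk = [p for p in (0.5, 0.95, 1.05, 1.4, 1.6) if min(1.0, lam) < p < max(1.0, lam)]
        ref_a = 200e3 * quad(lambda s: float(c.active_curve(s)), 1.0, lam, points=brk, limit=400)[0]
        ref_p = 200e3 * quad(lambda s: float(c.passive_curve(s)), 1.0, lam, points=brk, limit=400)[0]
        assert float(psi_a) == pytest.approx(ref_a, rel=1e-10, abs=1e-6)
        assert float(psi_p) == pytest.approx(ref_p, rel=1e-10, abs=1e-6)

    def test_yeoh_polynomial_oracle(self, muscle):
        # direct evaluation of the cubic in (I1_bar - 3)
        x = 0.2
        c = muscle.yeoh
        expected = muscle.s_base * (c.c1 * x + c.c2 * x**2 + c.c3 * x**3)
        assert float(base_energy_density(3.2, muscle)) == pytest.approx(expected, rel=1e-14)

    def test_base_energy_zero_at_reference_and_scales_with_s_base(self):
        m1 = TissueMaterial.muscle(s_base=1.0)
        m15 = TissueMaterial.muscle(s_base=1.5)
        assert float(base_energy_density(3.0, m1)) == 0.0
        ratio = float(base_energy_density(3.1, m15)) / float(base_energy_density(3.1, m1))
        assert ratio == pytest.approx(1.5, rel=1e-14)

    def test_base_energy_rejects_unattainable_invariant(self, muscle):
        with pytest.raises(ValueError):
            base_energy_density(2.9, muscle)

    def test_volumetric_energy_values_and_derivative(self, muscle):
        assert float(volumetric_energy_density(1.0, muscle)) == 0.0
        assert float(volumetric_energy_density(1.01, muscle)) == pytest.approx(50.0, rel=1e-12)
        J, h = 1.005, 1e-6
        fd = (float(volumetric_energy_density(J + h, muscle)) - float(volumetric_energy_density(J - h, muscle))) / (2 * h)
        assert float(muscle.vol.denergy(J)) == pytest.approx(fd, rel=1e-6)

    def test_volumetric_rejects_nonpositive_dilation(self, muscle):
        with pytest.raises(ElementInversionError):
            volumetric_energy_density(-0.1, muscle)


def _total_energy_density(C, a0, act, material):
    """Independent scalar energy used as the finite-difference oracle."""
    J = np.sqrt(np.linalg.det(C))
    lam = np.sqrt(a0 @ C @ a0)
    lam_bar = J ** (-1.0 / 3.0) * lam
    psi_a, psi_p = fibre_energy_density(lam_bar, act, material)
    i1_bar = J ** (-2.0 / 3.0) * np.trace(C)
    return float(psi_a) + float(psi_p) + float(base_energy_density(i1_bar, material)) \
        + float(volumetric_energy_density(J, material))


class TestPK2Components:
    def test_stress_free_reference(self, muscle):
        comps = pk2_stress_components(np.eye(3), 0.0, np.array([1.0, 0, 0]), 0.0, muscle)
        for key in ("active", "passive", "base", "volumetric", "total"):
            assert np.allclose(comps[key], 0.0, atol=1e-12)

    def test_active_stress_at_reference_is_deviatoric_along_fibre(self, muscle):
        # At F = I with full activation the active PK2 is the derivative of
        # sigma_max * int f(lambda_bar): sigma_max * (a0 a0 - I/3), computed
        # here independently by finite differences of the active energy alone.
        a0 = np.array([1.0, 0.0, 0.0])
        comps = pk2_stress_components(np.eye(3), 0.0, a0, 1.0, muscle)
        h = 1e-6
        expected = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                dC = np.zeros((3, 3))
                dC[i, j] += h / 2
                dC[j, i] += h / 2

                def psi_act(C):
                    J = np.sqrt(np.linalg.det(C))
                    lam_bar = J ** (-1 / 3) * np.sqrt(a0 @ C @ a0)
                    return float(fibre_energy_density(lam_bar, 1.0, muscle)[0])

                expected[i, j] = (psi_act(np.eye(3) + dC) - psi_act(np.eye(3) - dC)) / h
        assert np.allclose(comps["active"], expected, atol=2e-4 * 200e3)
        assert abs(np.trace(comps["active"]) ) < 1e-8  # deviatoric in Cauchy terms at C=I

    def test_element_inversion_raises(self, muscle):
        F = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ElementInversionError):
            pk2_stress_components(F, 0.0, np.array([1.0, 0, 0]), 0.0, muscle)

    def test_each_component_matches_fd_gradient_of_its_energy(self, muscle, rng):
        """Every PK2 component equals the central FD gradient of its own
        energy term w.r.t. the Green-Lagrange strain (100 random states)."""
        terms = {
            "active": lambda C, a0, act: float(fibre_energy_density(
                np.sqrt(np.linalg.det(C)) ** (-1 / 3) * np.sqrt(a0 @ C @ a0), act, muscle)[0]),
            "passive": lambda C, a0, act: float(fibre_energy_density(
                np.sqrt(np.linalg.det(C)) ** (-1 / 3) * np.sqrt(a0 @ C @ a0), act, muscle)[1]),
            "base": lambda C, a0, act: float(base_energy_density(
                np.linalg.det(C) ** (-1 / 3) * np.trace(C), muscle)),
            "volumetric": lambda C, a0, act: float(volumetric_energy_density(
                np.sqrt(np.linalg.det(C)), muscle)),
        }
        worst = 0.0
        for _ in range(100):
            F = _random_F(rng)
            a0 = _unit(rng)
            act = rng.uniform()
            C = F.T @ F
            J = np.linalg.det(F)
            p = muscle.vol.denergy(J)
            comps = pk2_stress_components(F, p, a0, act, muscle)
            h = 1e-6
            for key, psi in terms.items():
                fd = np.zeros((3, 3))
                for i in range(3):
                    for j in range(i, 3):
                        dC = np.zeros((3, 3))
                        dC[i, j] += h / 2
                        dC[j, i] += h / 2
                        fd[i, j] = fd[j, i] = (psi(C + dC, a0, act) - psi(C - dC, a0, act)) / h
                scale = max(np.max(np.abs(fd)), 1e3)
                worst = max(worst, np.max(np.abs(comps[key] - fd)) / scale)
        assert worst < 1e-5

    def test_frame_indifference_of_energies(self, muscle, rng):
        for _ in range(20):
            F = _random_F(rng)
            a0 = _unit(rng)
            Q = Rotation.random(random_state=np.random.RandomState(int(rng.integers(1 << 31)))).as_matrix()
            e1 = _total_energy_density(F.T @ F, a0, 0.6, muscle)
            e2 = _total_energy_density((Q @ F).T @ (Q @ F), a0, 0.6, muscle)
            assert abs(e1 - e2) <= 1e-10 * max(abs(e1), 1.0)

    def test_transverse_isotropy_about_fibre_axis(self, muscle, rng):
        a0 = np.array([1.0, 0.0, 0.0])
        for _ in range(20):
            F = _random_F(rng)
            ang = rng.uniform(0, 2 * np.pi)
            Q = Rotation.from_rotvec(ang * a0).as_matrix()
            FQ = F @ Q
            e1 = _total_energy_density(F.T @ F, a0, 0.8, muscle)
            e2 = _total_energy_density(FQ.T @ FQ, a0, 0.8, muscle)
            assert abs(e1 - e2) <= 1e-10 * max(abs(e1), 1.0)

    def test_component_additivity_is_exact(self, muscle, rng):
        F = _random_F(rng)
        comps = pk2_stress_components(F, 1e4, _unit(rng), 0.5, muscle)
        total = comps["active"] + comps["passive"] + comps["base"] + comps["volumetric"]
        assert np.array_equal(total, comps["total"])

    def test_s_base_affects_only_base_and_activation_only_active(self, rng):
        F = _random_F(rng)
        a0 = _unit(rng)
        m1, m15 = TissueMaterial.muscle(s_base=1.0), TissueMaterial.muscle(s_base=1.5)
        c_a = pk2_stress_components(F, 1e4, a0, 0.3, m1)
        c_b = pk2_stress_components(F, 1e4, a0, 0.3, m15)
        assert np.allclose(c_b["base"], 1.5 * c_a["base"], rtol=1e-13)
        for key in ("active", "passive", "volumetric"):
            assert np.array_equal(c_a[key], c_b[key])
        c_c = pk2_stress_components(F, 1e4, a0, 0.9, m1)
        for key in ("passive", "base", "volumetric"):
            assert np.array_equal(c_a[key], c_c[key])
        assert not np.allclose(c_a["active"], c_c["active"])


class TestMaterialDefinitions:
    def test_yeoh_fit_reproduces_frozen_coefficients(self):
        for pts, frozen in [
            (MUSCLE_BASE_CONTROL_POINTS, TissueMaterial.muscle().yeoh),
            (APONEUROSIS_BASE_CONTROL_POINTS, TissueMaterial.aponeurosis().yeoh),
        ]:
            c1, c2, c3 = fit_yeoh_uniaxial(pts)
            assert c1 == pytest.approx(frozen.c1, rel=1e-6, abs=1e-3)
            assert c2 == pytest.approx(frozen.c2, rel=1e-6, abs=1e-3)
            assert c3 == pytest.approx(frozen.c3, rel=1e-6, abs=1e-3)

    def test_negative_yeoh_coefficients_rejected(self):
        with pytest.raises(ValueError):
            YeohCoefficients(-1.0, 0.0, 0.0)

    def test_default_bulk_moduli(self):
        assert TissueMaterial.muscle().vol.kappa == 1e6
        assert TissueMaterial.aponeurosis().vol.kappa == 1e8

    def test_from_config_round_trip(self):
        cfg = {"kind": "muscle", "sigma_max": 150e3, "kappa": 2e6, "s_base": 1.5,
               "yeoh": [1e4, 2e4, 3e4]}
        m = TissueMaterial.from_config(cfg)
        assert m.sigma_max == 150e3
        assert m.vol.kappa == 2e6
        assert m.s_base == 1.5
        assert (m.yeoh.c1, m.yeoh.c2, m.yeoh.c3) == (1e4, 2e4, 3e4)
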