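"""Tests for the membrane constitutive laws and nodal force assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capsuleflow.membrane_mechanics import (
    Membrane,
    bending_forces,
    nodal_forces,
    sk_stresses,
    strain_energy,
    viscous_stress,
)
from capsuleflow.surface_mesh import make_sphere_mesh

stretch = st.floats(min_value=0.5, max_value=2.0)


class TestSkalakLaw:
    def test_undeformed_state_is_stress_free(self):
        t1, t2 = sk_stresses(1.0, 1.0, 5.0e-3, 37.0)
        assert t1 == 0.0 and t2 == 0.0

    def test_equibiaxial_small_stretch(self):
        lam = 1.01
        t1, t2 = sk_stresses(lam, lam, 1.0, 1.0)
        expected = (lam**2 - 1) + lam**2 * (lam**4 - 1)
        assert t1 == pytest.approx(expected, rel=1e-12)
        assert t2 == pytest.approx(expected, rel=1e-12)
        assert t1 == pytest.approx(0.06152, abs=2e-5)

    def test_uniaxial_example(self):
        t1, t2 = sk_stresses(1.1, 1.0, 1.0, 1.0)
        assert t1 == pytest.approx(0.462, abs=5e-4)
        assert t2 == pytest.approx(0.231, abs=5e-4)

    def test_energy_values(self):
        assert strain_energy(1.0, 1.0, 1.0, 1.0) == 0.0
        assert strain_energy(1.1, 1.0, 1.0, 1.0) == pytest.approx(
            0.02205, abs=1e-5)

    @given(stretch, stretch)
    @settings(max_examples=100, deadline=None)
    def test_energy_non_negative(self, l1, l2):
        W = strain_energy(l1, l2, 1.0, 1.0)
        assert W >= -1e-14
        if abs(l1 - 1) > 1e-3 or abs(l2 - 1) > 1e-3:
            assert W > 0

    @given(stretch, stretch,
           st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=100, deadline=None)
    def test_stresses_match_energy_gradient(self, l1, l2, C):
        """tau_i = (1/lambda_j) dW/dlambda_i, checked by central differences."""
        h = 1e-6
        t1, t2 = sk_stresses(l1, l2, 1.0, C)
        dW1 = (strain_energy(l1 + h, l2, 1.0, C)
               - strain_energy(l1 - h, l2, 1.0, C)) / (2 * h)
        dW2 = (strain_energy(l1, l2 + h, 1.0, C)
               - strain_energy(l1, l2 - h, 1.0, C)) / (2 * h)
        assert t1 == pytest.approx(dW1 / l2, rel=1e-6, abs=1e-8)
        assert t2 == pytest.approx(dW2 / l1, rel=1e-6, abs=1e-8)

    def test_small_strain_dilatation_modulus(self):
        """Isotropic dilation limit: tau ~ Ks (lambda1*lambda2 - 1)."""
        for C in (1.0, 10.0, 25.0):
            lam = 1.0005
            t1, _ = sk_stresses(lam, lam, 1.0, C)
            Ks = 1.0 + 2.0 * C
            assert t1 == pytest.approx(Ks * (lam**2 - 1), rel=0.01)

    def test_rejects_non_positive_stretch(self):
        with pytest.raises(ValueError):
            sk_stresses(0.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            strain_energy(1.0, -0.5, 1.0, 1.0)


class TestViscousStress:
    def test_zero_strain_rate(self):
        assert np.allclose(viscous_stress(np.zeros((2, 2)), mu_s=5.0), 0.0)

    def test_pure_shear(self):
        D = np.array([[0.3, 0.1], [0.1, -0.3]])  # traceless
        tau = viscous_stress(D, mu_s=2.0)
        assert np.allclose(tau, 4.0 * D)

    def test_isotropic_dilation_cancels_without_dilatational_viscosity(self):
        D = 0.7 * np.eye(2)
        assert np.allclose(viscous_stress(D, mu_s=3.0, mu_s_dil=0.0), 0.0,
                           atol=1e-14)

    def test_dilatational_part(self):
        D = 0.5 * np.eye(2)
        tau = viscous_stress(D, mu_s=0.0, mu_s_dil=2.0)
        assert np.allclose(tau, 2.0 * np.eye(2))

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            viscous_stress(np.array([[0.0, 1.0], [0.0, 0.0]]), mu_s=1.0)

    def test_dissipation_non_negative(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            A = rng.normal(size=(2, 2))
            D = (A + A.T) / 2
            tau = viscous_stress(D, mu_s=1.3)
            assert np.einsum("ij,ij->", tau, D) >= -1e-14


class TestBending:
    def test_sphere_helfrich_energy(self):
        m = make_sphere_mesh(3, 1.0)
        Eb, _ = bending_forces(m, kc=1.0)
        assert Eb == pytest.approx(8 * np.pi, rel=0.03)

    def test_energy_improves_under_refinement(self):
        e = []
        for n in (2, 3, 4):
            Eb, _ = bending_forces(make_sphere_mesh(n, 1.0), kc=1.0)
            e.append(abs(Eb - 8 * np.pi))
        assert e[2] < e[1] < e[0]

    def test_scale_invariance(self):
        e1, _ = bending_forces(make_sphere_mesh(3, 1.0e-6), kc=1.0)
        e2, _ = bending_forces(make_sphere_mesh(3, 5.0e-6), kc=1.0)
        assert e1 == pytest.approx(e2, rel=1e-9)

    def test_forces_sum_to_zero(self):
        m = make_sphere_mesh(3, 1.0)
        m.vertices = m.vertices * np.array([1.3, 1.0, 0.8])
        _, f = bending_forces(m, kc=1.0)
        scale = np.abs(f).max()
        assert np.abs(f.sum(axis=0)).max() < 1e-6 * scale


class TestNodalForces:
    def test_undeformed_sphere_force_free(self):
        m = make_sphere_mesh(3, 1.0)
        state = nodal_forces(m, Gs=1.0, C=1.0, kc=0.0)
        assert np.abs(state.nodal_forces).max() < 1e-12

    def test_inflated_sphere_matches_laplace_law(self):
        a, lam = 1.0, 1.05
        m = make_sphere_mesh(3, a)
        m.vertices = m.vertices * lam
        state = nodal_forces(m, Gs=1.0, C=1.0, kc=0.0)
        t1, _ = sk_stresses(lam, lam, 1.0, 1.0)
        normals = m.vertices / np.linalg.norm(m.vertices, axis=1,
                                              keepdims=True)
        p_eq = -(state.nodal_forces * normals).sum() / (4 * np.pi * (lam * a) ** 2)
        assert p_eq == pytest.approx(2 * t1 / (lam * a), rel=0.02)

    def test_resultant_force_and_torque_vanish(self):
        rng = np.random.default_rng(3)
        m = make_sphere_mesh(3, 1.0)
        m.vertices = m.vertices * (1 + 0.1 * rng.normal(size=(m.n_vertices, 1)))
        state = nodal_forces(m, Gs=1.0, C=5.0, kc=0.0,
                             previous_vertices=m.vertices * 0.99, dt=1.0,
                             mu_s=0.5)
        f = state.nodal_forces
        scale = np.abs(f).max() * m.n_vertices
        assert np.abs(f.sum(axis=0)).max() < 1e-12 * scale
        torque = np.cross(m.vertices, f).sum(axis=0)
        assert np.abs(torque).max() < 1e-12 * scale

    def test_membrane_dissipation_non_negative(self):
        rng = np.random.default_rng(11)
        m = make_sphere_mesh(2, 1.0)
        prev = m.vertices * (1 + 0.02 * rng.normal(size=(m.n_vertices, 1)))
        state = nodal_forces(m, Gs=0.0, C=0.0, kc=0.0, mu_s=1.0,
                             previous_vertices=prev, dt=0.5)
        D = state.kinematics.D
        diss = 1.0 * ((D[:, 0, 0] - D[:, 1, 1]) ** 2 + 4 * D[:, 0, 1] ** 2)
        assert np.all(diss >= -1e-14)
        # tau^v : D equals the same expression for mu_s = 1
        assert np.einsum("eij,eij->e", state.tau, D) == pytest.approx(
            diss, rel=1e-9)

    def test_membrane_class_advance(self):
        m = make_sphere_mesh(2, 1.0e-6)
        mem = Membrane(m, Gs=1e-3, C=10.0, mu_s=1e-6, kc=1e-18)
        f0 = mem.forces(1e-8)
        assert np.all(np.isfinite(f0))
        m.vertices *= 1.01
        f1 = mem.forces(1e-8)
        assert np.abs(f1).max() > np.abs(f0).max()
        mem.advance()
        assert np.allclose(mem.prev_vertices, m.vertices)
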