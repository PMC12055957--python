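"""Tests for immersed-boundary coupling and the indicator field."""

import numpy as np
import pytest

from capsuleflow import _ibm_kernels as ik
from capsuleflow.coupling_ibm import (
    blended_viscosity,
    indicator_volume,
    interpolate_velocity,
    ray_cast_indicator,
    spread_forces,
    update_indicator,
)
from capsuleflow.fluid_lbm import LatticeConfig, LatticeField
from capsuleflow.params import FluidModel, power_law_viscosity
from capsuleflow.surface_mesh import make_sphere_mesh


@pytest.fixture()
def box_field():
    n = 40
    flags = np.ones((n, n, n), dtype=np.uint8)
    cfg = LatticeConfig(dx=1e-6, dt=1e-7, fluid=FluidModel())
    return LatticeField(flags, cfg, periodic=(True, True, True))


CENTRE = (20e-6, 20e-6, 20e-6)


class TestPeskinKernel:
    def test_partition_of_unity(self):
        for r in np.linspace(-0.5, 0.5, 11):
            s = sum(ik.peskin4(r - t) for t in range(-2, 3))
            assert s == pytest.approx(1.0, abs=1e-14)

    def test_first_moment(self):
        for r in np.linspace(-0.5, 0.5, 11):
            m = sum(t * ik.peskin4(r - t) for t in range(-3, 4))
            assert m == pytest.approx(r, abs=1e-13)

    def test_symmetry_and_support(self):
        assert ik.peskin4(0.7) == pytest.approx(ik.peskin4(-0.7))
        assert ik.peskin4(2.0) == 0.0
        assert ik.peskin4(0.0) == pytest.approx(
            (3 + 1) / 8)  # phi(0) = 1/2


class TestSpreading:
    def test_single_marker_weights_sum_to_one(self, box_field):
        pos = np.array([[20.3e-6, 20.1e-6, 19.8e-6]])
        F = np.array([[1.0e-9, 0.0, 0.0]])
        spread_forces(box_field, pos, F, accumulate=False)
        cfg = box_field.config
        fac = cfg.dt**2 / (cfg.fluid.rho * cfg.dx**4)
        assert box_field.force[:, 0].sum() == pytest.approx(1e-9 * fac,
                                                            rel=1e-12)

    def test_total_force_conserved(self, box_field):
        mesh = make_sphere_mesh(3, 8e-6, CENTRE)
        rng = np.random.default_rng(5)
        F = rng.normal(size=mesh.vertices.shape) * 1e-9
        spread_forces(box_field, mesh.vertices, F, accumulate=False)
        cfg = box_field.config
        fac = cfg.dt**2 / (cfg.fluid.rho * cfg.dx**4)
        total = box_field.force.sum(axis=0) / fac
        assert np.abs(total - F.sum(axis=0)).max() < 1e-12 * np.abs(
            F.sum(axis=0)).max()

    def test_marker_on_lattice_point_symmetric_peak(self, box_field):
        # lattice node 20 sits at physical (20 + 0.5) dx
        pos = np.array([[20.5e-6, 20.5e-6, 20.5e-6]])
        spread_forces(box_field, pos, np.array([[1e-9, 0, 0]]),
                      accumulate=False)
        f3 = box_field.view3d(box_field.force)[..., 0]
        peak = np.unravel_index(np.argmax(f3), f3.shape)
        assert peak == (20, 20, 20)
        assert f3[19, 20, 20] == pytest.approx(f3[21, 20, 20], rel=1e-12)


class TestInterpolation:
    def test_uniform_field_exact(self, box_field):
        box_field.u[:, 0] = 0.004
        mesh = make_sphere_mesh(2, 8e-6, CENTRE)
        v = interpolate_velocity(box_field, mesh.vertices)
        u_phys = 0.004 * box_field.config.dx / box_field.config.dt
        assert np.allclose(v[:, 0], u_phys, rtol=1e-13)
        assert np.allclose(v[:, 1:], 0.0, atol=1e-16)

    def test_linear_field_exact(self, box_field):
        u3 = box_field.view3d(box_field.u)
        X = np.arange(40, dtype=float)[:, None, None]
        u3[..., 1] = 1e-4 * X + 3e-3
        mesh = make_sphere_mesh(2, 8e-6, CENTRE)
        v = interpolate_velocity(box_field, mesh.vertices)
        x_lat = mesh.vertices[:, 0] / box_field.config.dx - 0.5
        expected = (1e-4 * x_lat + 3e-3) * (
            box_field.config.dx / box_field.config.dt)
        assert np.allclose(v[:, 1], expected, rtol=1e-12)

    def test_adjointness_power_balance(self, box_field):
        """sum_v F.u(X_v) equals the lattice integral of f.u exactly."""
        rng = np.random.default_rng(9)
        u3 = box_field.view3d(box_field.u)
        u3[:] = rng.normal(size=u3.shape) * 1e-3
        mesh = make_sphere_mesh(3, 8e-6, CENTRE)
        F = rng.normal(size=mesh.vertices.shape) * 1e-9
        spread_forces(box_field, mesh.vertices, F, accumulate=False)
        v = interpolate_velocity(box_field, mesh.vertices)
        lhs = np.sum(F * v)
        cfg = box_field.config
        fac = cfg.dt**2 / (cfg.fluid.rho * cfg.dx**4)
        u_phys = box_field.u * (cfg.dx / cfg.dt)
        rhs = np.sum((box_field.force / fac) * u_phys)
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestIndicator:
    def test_sphere_indicator(self, box_field):
        a = 8e-6
        mesh = make_sphere_mesh(3, a, CENTRE)
        update_indicator(box_field, mesh)
        I3 = box_field.view3d(box_field.Icell)
        assert I3[20, 20, 20] == pytest.approx(1.0, abs=0.02)
        assert I3[2, 2, 2] == pytest.approx(0.0, abs=1e-6)
        # volume integral vs the mesh's enclosed volume
        from capsuleflow import _mesh_kernels as mk

        vol_mesh = mk.enclosed_volume(mesh.vertices, mesh.triangles)
        assert indicator_volume(box_field, "cell") == pytest.approx(
            vol_mesh, rel=0.02)

    def test_half_level_set_near_true_radius(self, box_field):
        a = 8e-6
        mesh = make_sphere_mesh(3, a, CENTRE)
        update_indicator(box_field, mesh)
        I3 = box_field.view3d(box_field.Icell)
        row = I3[20:34, 20, 20]
        # I crosses 0.5 within half a cell of the sphere surface
        xc = np.interp(-0.5, -row, np.arange(20, 34, dtype=float))
        x_phys = (xc + 0.5) * 1e-6
        assert abs(x_phys - (20e-6 + a)) < 0.5e-6

    def test_indicator_matches_ray_cast_oracle(self, box_field):
        mesh = make_sphere_mesh(3, 8e-6, CENTRE)
        update_indicator(box_field, mesh)
        inside = ray_cast_indicator(box_field, mesh)
        I = box_field.view3d(box_field.Icell)
        # interface is smeared over ~2 cells, so compare region means and
        # the deep interior (3 cells inside the surface)
        assert I[inside].mean() > 0.8
        assert I[~inside].mean() < 0.02
        r = np.linalg.norm(
            (np.moveaxis(np.indices(I.shape), 0, -1) + 0.5) * 1e-6
            - np.array(CENTRE), axis=-1)
        assert I[r < 8e-6 - 3e-6].min() > 0.95

    def test_no_cell_gives_zero(self, box_field):
        assert np.all(box_field.Icell == 0.0)
        assert indicator_volume(box_field, "cell") == 0.0

    def test_nucleus_bounded_by_cell(self, box_field):
        cell = make_sphere_mesh(3, 8e-6, CENTRE)
        nuc = make_sphere_mesh(2, 4e-6, CENTRE)
        update_indicator(box_field, cell, nuc)
        assert np.all(box_field.Inuc <= box_field.Icell + 1e-12)


class TestBlendedViscosity:
    def test_uniform_exterior(self, box_field):
        fl = box_field.config.fluid
        gd_star = (fl.mu0 / fl.K) ** (1 / (fl.alpha - 1)) * fl.gamma0
        box_field.gamma_dot[:] = gd_star
        mu = blended_viscosity(box_field, lam=1.0)
        assert np.allclose(mu, fl.mu0, rtol=1e-10)

    def test_interior_is_newtonian(self, box_field):
        box_field.Icell[:] = 1.0
        box_field.gamma_dot[:] = 12345.0
        mu = blended_viscosity(box_field, lam=2.0)
        assert np.allclose(mu, 2.0 * box_field.config.fluid.mu0)

    def test_volume_weighted_mixture(self, box_field):
        a = 8e-6
        mesh = make_sphere_mesh(3, a, CENTRE)
        update_indicator(box_field, mesh)
        fl = box_field.config.fluid
        gd_star = (fl.mu0 / fl.K) ** (1 / (fl.alpha - 1)) * fl.gamma0
        box_field.gamma_dot[:] = gd_star
        mu = blended_viscosity(box_field, lam=2.0)
        V_box = (40e-6) ** 3
        V_cell = indicator_volume(box_field, "cell")
        expected = fl.mu0 * (V_box - V_cell) / V_box + 2 * fl.mu0 * V_cell / V_box
        assert mu.mean() == pytest.approx(expected, rel=0.02)


class TestRigidTranslation:
    def test_sphere_advects_with_uniform_flow(self):
        """A force-free sphere in uniform flow translates at the flow speed
        with negligible volume drift."""
        n = 36
        flags = np.ones((n, n, n), dtype=np.uint8)
        cfg = LatticeConfig(dx=1e-6, dt=1e-7, fluid=FluidModel())
        fld = LatticeField(flags, cfg, periodic=(True, True, True))
        U0 = 0.02  # m/s
        fld.initialize(u0=(cfg.u_lat(U0), 0.0, 0.0))
        from capsuleflow import _mesh_kernels as mk

        mesh = make_sphere_mesh(3, 6e-6, (12e-6, 18e-6, 18e-6))
        v0 = mk.enclosed_volume(mesh.vertices, mesh.triangles)
        x0 = mesh.centroid()[0]
        nsteps = 1000
        for _ in range(nsteps):
            fld.step(1)
            v = interpolate_velocity(fld, mesh.vertices)
            mesh.vertices += v * cfg.dt
        dx_c = mesh.centroid()[0] - x0
        assert dx_c == pytest.approx(U0 * nsteps * cfg.dt, rel=1e-3)
        v1 = mk.enclosed_volume(mesh.vertices, mesh.triangles)
        assert abs(v1 / v0 - 1) < 1e-3
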