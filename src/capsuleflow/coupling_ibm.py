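"""Immersed-boundary coupling and the front-tracking indicator field.

Membrane nodal forces are spread onto the lattice with the 4-point Peskin
kernel, and lattice velocities are interpolated back at the membrane
vertices with the same kernel (adjoint pair, so the discrete power balance
holds).  The cytoplasm/nucleus viscosity contrast is carried by indicator
(colour) functions I in [0, 1], reconstructed from the instantaneous
membrane geometry by solving the Poisson problem

    div grad I = div G,     G = spread(-n_out dA),

on a sub-box around the cell with homogeneous Dirichlet boundary (zero far
field), the standard front-tracking construction.  Because I is rebuilt
from the current interface each time, it cannot drift.
"""

from __future__ import annotations

import numpy as np
import scipy.fft

from . import _ibm_kernels as ik
from . import _mesh_kernels as mk
from .fluid_lbm import LatticeField
from .surface_mesh import TriMesh

__all__ = [
    "spread_forces",
    "interpolate_velocity",
    "advect_vertices",
    "update_indicator",
    "blended_viscosity",
    "indicator_volume",
]


def _to_lattice(field: LatticeField, x_phys: np.ndarray) -> np.ndarray:
    """Physical positions (m) -> lattice coordinates (node i at i)."""
    origin = getattr(field, "origin", None)
    if origin is None:
        return x_phys / field.config.dx - 0.5
    return (x_phys - origin) / field.config.dx - 0.5


def spread_forces(field: LatticeField, positions_phys: np.ndarray,
                  forces_N: np.ndarray, accumulate: bool = True) -> None:
    """Spread vertex forces (N) into the lattice force-density field.

    Total spread force equals the total vertex force exactly (kernel
    partition of unity) provided no stencil is clipped by the domain edge.
    """
    nx, ny, nz = field.shape
    if not accumulate:
        field.force[:] = 0.0
    pos = _to_lattice(field, np.ascontiguousarray(positions_phys, dtype=float))
    cfg = field.config
    # F_vertex (N) -> lattice force density: F dt^2 / (rho dx^4)
    fac = cfg.dt**2 / (cfg.fluid.rho * cfg.dx**4)
    vals = np.ascontiguousarray(forces_N, dtype=float) * fac
    clipped = ik.spread(pos, vals, field.force, nx, ny, nz)
    if clipped:
        lo = pos.min(axis=0)
        hi = pos.max(axis=0)
        raise ValueError(
            f"{clipped} membrane vertices within 2 cells of the domain edge "
            f"(lattice extent [{lo}, {hi}], box {(nx, ny, nz)})"
        )


def interpolate_velocity(field: LatticeField,
                         positions_phys: np.ndarray) -> np.ndarray:
    """Interpolate the fluid velocity (m/s) at the given positions."""
    nx, ny, nz = field.shape
    pos = _to_lattice(field, np.ascontiguousarray(positions_phys, dtype=float))
    out = np.empty_like(pos)
    ik.interp(field.u, pos, out, nx, ny, nz)
    return out * (field.config.dx / field.config.dt)


def advect_vertices(field: LatticeField, mesh: TriMesh, dt: float) -> None:
    """Explicit Euler vertex advection with the interpolated velocity."""
    v = interpolate_velocity(field, mesh.vertices)
    mesh.vertices += v * dt


def _poisson_dirichlet(rhs: np.ndarray) -> np.ndarray:
    """Solve div grad I = rhs (unit spacing) with I = 0 outside the box."""
    m1, m2, m3 = rhs.shape
    k1 = 2.0 * np.cos(np.pi * np.arange(1, m1 + 1) / (m1 + 1)) - 2.0
    k2 = 2.0 * np.cos(np.pi * np.arange(1, m2 + 1) / (m2 + 1)) - 2.0
    k3 = 2.0 * np.cos(np.pi * np.arange(1, m3 + 1) / (m3 + 1)) - 2.0
    lam = k1[:, None, None] + k2[None, :, None] + k3[None, None, :]
    rhat = scipy.fft.dstn(rhs, type=1)
    ihat = rhat / lam
    return scipy.fft.idstn(ihat, type=1)


def _indicator_box(field: LatticeField, mesh: TriMesh,
                   margin: int = 4) -> tuple[np.ndarray, tuple]:
    """Indicator values on a sub-box around one mesh."""
    nx, ny, nz = field.shape
    pos = _to_lattice(field, mesh.vertices)
    lo = np.maximum(np.floor(pos.min(axis=0)).astype(int) - margin, 0)
    hi = np.minimum(np.ceil(pos.max(axis=0)).astype(int) + margin,
                    np.array([nx - 1, ny - 1, nz - 1]))
    dims = hi - lo + 1
    area, normal, cent = mk.tri_geometry(mesh.vertices, mesh.triangles)
    cent_lat = _to_lattice(field, cent)
    # -n_out * dA in lattice units
    vec = -normal * (area / field.config.dx**2)[:, None]
    G = np.zeros((dims[0], dims[1], dims[2], 3))
    ik.spread_scalar_box(cent_lat, vec, lo.astype(float), G)
    div = np.zeros(G.shape[:3])
    div[1:-1, :, :] += 0.5 * (G[2:, :, :, 0] - G[:-2, :, :, 0])
    div[:, 1:-1, :] += 0.5 * (G[:, 2:, :, 1] - G[:, :-2, :, 1])
    div[:, :, 1:-1] += 0.5 * (G[:, :, 2:, 2] - G[:, :, :-2, 2])
    I = _poisson_dirichlet(div)
    np.clip(I, 0.0, 1.0, out=I)
    return I, (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1),
               slice(lo[2], hi[2] + 1))


def update_indicator(field: LatticeField, cell_mesh: TriMesh,
                     nucleus_mesh: TriMesh | None = None) -> None:
    """Rebuild the cell (and nucleus) indicator fields from the meshes."""
    Ic3 = field.view3d(field.Icell)
    Ic3[:] = 0.0
    I, sl = _indicator_box(field, cell_mesh)
    Ic3[sl] = I
    In3 = field.view3d(field.Inuc)
    In3[:] = 0.0
    if nucleus_mesh is not None:
        In, sln = _indicator_box(field, nucleus_mesh)
        In3[sln] = In
        np.minimum(field.Inuc, field.Icell, out=field.Inuc)


def blended_viscosity(field: LatticeField, lam: float = 1.0,
                      lam_nucleus: float | None = None) -> np.ndarray:
    """Diagnostic dynamic-viscosity field (Pa s) on the 3D lattice."""
    fl = field.config.fluid
    from .params import power_law_viscosity

    mu_ext = power_law_viscosity(np.maximum(field.gamma_dot, 0.0), fl)
    Ic = np.clip(field.Icell, 0.0, 1.0)
    In = np.clip(field.Inuc, 0.0, Ic)
    lam_n = lam if lam_nucleus is None else lam_nucleus
    mu = mu_ext * (1.0 - Ic) + lam * fl.mu0 * (Ic - In) + lam_n * fl.mu0 * In
    return field.view3d(mu)


def indicator_volume(field: LatticeField, which: str = "cell") -> float:
    """Integral of an indicator field (m^3)."""
    arr = field.Icell if which == "cell" else field.Inuc
    return float(arr.sum()) * field.config.dx**3


def ray_cast_indicator(field: LatticeField, mesh: TriMesh) -> np.ndarray:
    """Sharp inside/outside field by crossing-parity ray casting (oracle)."""
    nx, ny, nz = field.shape
    verts = _to_lattice(field, mesh.vertices)
    pos = verts
    lo = np.maximum(np.floor(pos.min(axis=0)).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(pos.max(axis=0)).astype(int) + 1,
                    np.array([nx - 1, ny - 1, nz - 1]))
    ys = np.arange(lo[1], hi[1] + 1)
    zs = np.arange(lo[2], hi[2] + 1)
    YY, ZZ = np.meshgrid(ys, zs, indexing="ij")
    lines = np.column_stack([YY.ravel(), ZZ.ravel()]).astype(float)
    inside = np.zeros((len(lines), hi[0] - lo[0] + 1), dtype=np.bool_)
    ik.ray_cast_inside(lines, lo[0], hi[0], verts,
                       mesh.triangles, inside)
    out = np.zeros(field.shape, dtype=bool)
    out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = (
        inside.reshape(len(ys), len(zs), -1).transpose(2, 0, 1)
    )
    return out
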