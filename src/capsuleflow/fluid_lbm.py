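"""D3Q19 lattice-Boltzmann solver for the suspending power-law fluid.

BGK single-relaxation collision with Guo forcing; the local relaxation time
is set every step from the truncated power-law viscosity evaluated at the
shear rate reconstructed from non-equilibrium moments, blended with the
Newtonian interior viscosities through the cell/nucleus indicator fields.
Walls use Bouzidi linear interpolated bounce-back (per-link fluid fractions
q); inlets and outlets impose density (pressure) through non-equilibrium
extrapolation.

Unit mapping: a lattice spacing ``dx`` (m) and time step ``dt`` (s) define
velocity, viscosity and force-density scales

    u_lat = u dt/dx,   nu_lat = nu dt/dx^2,   F_lat = F dt^2 / (rho dx),

with lattice density 1 at the physical density ``rho``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import _lbm_kernels as lk
from .params import FluidModel

__all__ = ["LatticeConfig", "LatticeField", "lbm_step", "local_shear_rate",
           "apply_bounce_back", "pressure_bc"]

SOLID, FLUID, INLET, OUTLET = lk.SOLID, lk.FLUID, lk.INLET, lk.OUTLET


@njit(cache=True)
def _classify(flags3d, px, py, pz):
    """Split non-solid nodes into interior (fast streaming) and boundary."""
    nx, ny, nz = flags3d.shape
    N = nx * ny * nz
    kind = np.zeros(N, dtype=np.uint8)  # 0 solid, 1 interior, 2 boundary
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if flags3d[ix, iy, iz] == lk.SOLID:
                    continue
                n = (ix * ny + iy) * nz + iz
                interior = True
                for i in range(1, 19):
                    sx = ix - lk.C[i, 0]
                    sy = iy - lk.C[i, 1]
                    sz = iz - lk.C[i, 2]
                    if not (0 <= sx < nx and 0 <= sy < ny and 0 <= sz < nz):
                        interior = False
                        break
                    if flags3d[sx, sy, sz] == lk.SOLID:
                        interior = False
                        break
                kind[n] = 1 if interior else 2
    return kind


@dataclass(frozen=True)
class LatticeConfig:
    """Resolution and unit mapping of one lattice."""

    dx: float  # m per lattice unit
    dt: float  # s per step
    fluid: FluidModel

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")

    # --- conversions ------------------------------------------------------
    def u_lat(self, u_phys: float) -> float:
        return u_phys * self.dt / self.dx

    def u_phys(self, u_lat):
        return u_lat * self.dx / self.dt

    def nu_lat(self, nu_phys: float) -> float:
        return nu_phys * self.dt / self.dx**2

    def force_density_lat(self, f_phys):
        return f_phys * self.dt**2 / (self.fluid.rho * self.dx)

    def pressure_to_drho(self, dp_phys: float) -> float:
        """Lattice density offset equivalent to a physical pressure offset."""
        return 3.0 * dp_phys * self.dt**2 / (self.fluid.rho * self.dx**2)

    @property
    def tau0(self) -> float:
        """Relaxation time at the characteristic viscosity mu0."""
        return 3.0 * self.nu_lat(self.fluid.mu0 / self.fluid.rho) + 0.5


class LatticeField:
    """Populations, macroscopic fields and boundary data on one lattice.

    Macroscopic arrays are flat (N,) / (N, 3) over the C-ordered (nx, ny,
    nz) box; ``view3d`` reshapes them back.
    """

    def __init__(self, flags: np.ndarray, config: LatticeConfig,
                 qlink: np.ndarray | None = None,
                 periodic=(False, False, False),
                 origin=(0.0, 0.0, 0.0)):
        self.config = config
        self.origin = np.asarray(origin, dtype=float)
        self.flags3d = np.ascontiguousarray(flags, dtype=np.uint8)
        nx, ny, nz = self.flags3d.shape
        self.shape = (nx, ny, nz)
        N = nx * ny * nz
        self.N = N
        self.flags = self.flags3d.reshape(-1)
        self.periodic = tuple(bool(p) for p in periodic)
        kind = _classify(self.flags3d, *self.periodic)
        self.nonsolid = np.flatnonzero(kind != 0).astype(np.int64)
        self.interior = np.flatnonzero(kind == 1).astype(np.int64)
        self.boundary = np.flatnonzero(kind == 2).astype(np.int64)
        self.noff = (lk.C[:, 0] * ny + lk.C[:, 1]) * nz + lk.C[:, 2]
        self.f = np.zeros((N, 19))
        self.fpost = np.zeros_like(self.f)
        if qlink is None:
            qlink = np.full((N, 19), -1.0, dtype=np.float64)
        self.qlink = np.ascontiguousarray(qlink, dtype=np.float64).reshape(N, 19)
        self.tau = np.full(N, config.tau0)
        self.force = np.zeros((N, 3))
        self.rho = np.ones(N)
        self.u = np.zeros((N, 3))
        self.gamma_dot = np.zeros(N)  # physical 1/s
        self.Icell = np.zeros(N)
        self.Inuc = np.zeros(N)
        self.wall_u = np.zeros((N, 3))  # lattice units; moving-wall tests
        self.nu_cyt_lat = config.nu_lat(config.fluid.mu0 / config.fluid.rho)
        self.nu_nuc_lat = self.nu_cyt_lat
        self._bc_nodes = np.zeros(0, dtype=np.int64)
        self._bc_nbr = np.zeros(0, dtype=np.int64)
        self._bc_rho = np.zeros(0)
        self._btab = None
        self.time = 0.0
        self.steps = 0
        self.initialize()

    # --- helpers ----------------------------------------------------------
    def view3d(self, arr: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.shape
        if arr.ndim == 1:
            return arr.reshape(nx, ny, nz)
        return arr.reshape(nx, ny, nz, arr.shape[-1])

    def flat_index(self, ix, iy, iz):
        nx, ny, nz = self.shape
        return (np.asarray(ix) * ny + np.asarray(iy)) * nz + np.asarray(iz)

    # --- setup ------------------------------------------------------------
    def initialize(self, rho0: float = 1.0, u0=(0.0, 0.0, 0.0)) -> None:
        lk.init_equilibrium(self.f, self.nonsolid, rho0,
                            np.asarray(u0, dtype=float))
        lk.macros(self.f, self.nonsolid, self.force, self.rho, self.u)

    def set_viscosity_ratio(self, lam: float, lam_nucleus: float | None = None):
        """Newtonian interior viscosities as multiples of mu0."""
        nu0 = self.config.fluid.mu0 / self.config.fluid.rho
        self.nu_cyt_lat = self.config.nu_lat(lam * nu0)
        self.nu_nuc_lat = self.config.nu_lat(
            (lam if lam_nucleus is None else lam_nucleus) * nu0
        )

    def set_pressure_boundaries(self, planes) -> None:
        """Define density boundaries.

        ``planes`` is a list of (axis, side, rho_target) with axis in
        {0, 1, 2} and side in {0, -1}; every non-solid node of that face
        becomes a BC node whose interior neighbour is one node inward.
        """
        nodes = []
        nbrs = []
        rhos = []
        for axis, side, rho_t in planes:
            if axis not in (0, 1, 2):
                raise ValueError("plane must be axis-aligned (axis 0, 1 or 2)")
            idx = 0 if side == 0 else self.shape[axis] - 1
            inward = 1 if side == 0 else -1
            face = np.take(self.flags3d, idx, axis=axis)
            for ab in np.argwhere(face != SOLID):
                node = [0, 0, 0]
                node[axis] = idx
                other = [a for a in range(3) if a != axis]
                node[other[0]] = int(ab[0])
                node[other[1]] = int(ab[1])
                nbr = list(node)
                nbr[axis] += inward
                if self.flags3d[nbr[0], nbr[1], nbr[2]] == SOLID:
                    continue
                nodes.append(self.flat_index(*node))
                nbrs.append(self.flat_index(*nbr))
                rhos.append(rho_t)
        self._bc_nodes = np.asarray(nodes, dtype=np.int64)
        self._bc_nbr = np.asarray(nbrs, dtype=np.int64)
        self._bc_rho = np.asarray(rhos, dtype=float)

    def invalidate_boundaries(self) -> None:
        """Force a rebuild of the precomputed boundary streaming tables
        (call after changing qlink or wall velocities)."""
        self._btab = None

    def _boundary_tables(self):
        if self._btab is None:
            nx, ny, nz = self.shape
            px, py, pz = self.periodic
            self._btab = lk.build_boundary_tables(
                self.boundary, self.flags, self.qlink, self.wall_u,
                nx, ny, nz, px, py, pz,
            )
        return self._btab

    # --- stepping ---------------------------------------------------------
    visc_every: int = 1  # steps between shear-rate/viscosity refreshes

    def step(self, nsteps: int = 1) -> None:
        cfg = self.config
        fl = cfg.fluid
        nu_K = fl.K / fl.rho * fl.gamma0 ** (1.0 - fl.alpha) * cfg.dt / cfg.dx**2
        mode, srcA, cA, cB, mw = self._boundary_tables()
        for _ in range(nsteps):
            lk.collide(
                self.f, self.fpost, self.nonsolid, self.tau, self.force,
                self.Icell, self.Inuc,
                nu_K, fl.alpha, fl.gamma_min, fl.gamma_max, 1.0 / cfg.dt,
                self.nu_cyt_lat, self.nu_nuc_lat, self.gamma_dot,
                self.rho, self.u, self.steps % self.visc_every == 0,
            )
            lk.stream_interior(self.f, self.fpost, self.interior, self.noff)
            lk.stream_boundary_tab(self.f, self.fpost, self.boundary,
                                   mode, srcA, cA, cB, mw)
            if len(self._bc_nodes):
                lk.pressure_bc(self.f, self.rho, self.u, self._bc_nodes,
                               self._bc_nbr, self._bc_rho)
            self.steps += 1
            self.time += cfg.dt

    def refresh_macros(self) -> None:
        """Recompute density/velocity from the current populations."""
        lk.macros(self.f, self.nonsolid, self.force, self.rho, self.u)

    def check_stability(self) -> None:
        tau_ns = self.tau[self.nonsolid]
        if np.any(tau_ns <= 0.5):
            n = self.nonsolid[np.argmax(tau_ns <= 0.5)]
            raise RuntimeError(f"relaxation time <= 0.5 at flat node {n}")
        if not np.all(np.isfinite(self.u[self.nonsolid])):
            raise RuntimeError("non-finite velocity: time step too large")

    # --- diagnostics --------------------------------------------------------
    def velocity_phys(self) -> np.ndarray:
        """(nx, ny, nz, 3) velocity in m/s."""
        return self.view3d(self.u) * (self.config.dx / self.config.dt)

    def mass(self) -> float:
        return float(lk.total_mass(self.f, self.nonsolid))

    def flow_rate(self, axis: int = 0, index: int | None = None) -> float:
        """Volumetric flow rate (m^3/s) through a lattice plane."""
        if index is None:
            index = self.shape[axis] // 2
        u3 = self.view3d(self.u)[..., axis]
        u_ax = np.take(u3, index, axis=axis)
        mask = np.take(self.flags3d, index, axis=axis) != SOLID
        return float(
            u_ax[mask].sum() * (self.config.dx / self.config.dt)
            * self.config.dx**2
        )


# --- spec-level operation wrappers -----------------------------------------

def lbm_step(fieldobj: LatticeField, nsteps: int = 1) -> LatticeField:
    """Advance ``nsteps`` collide-force-stream cycles in place."""
    fieldobj.step(nsteps)
    fieldobj.check_stability()
    return fieldobj


def local_shear_rate(fieldobj: LatticeField) -> np.ndarray:
    """Physical shear rate (1/s) per node (3D view)."""
    return fieldobj.view3d(fieldobj.gamma_dot)


def apply_bounce_back(fieldobj: LatticeField) -> LatticeField:
    """Re-run the streaming (wall bounce-back) part only, for testing."""
    px, py, pz = fieldobj.periodic
    nx, ny, nz = fieldobj.shape
    lk.stream_interior(fieldobj.f, fieldobj.fpost, fieldobj.interior,
                       fieldobj.noff)
    lk.stream_boundary(fieldobj.f, fieldobj.fpost, fieldobj.boundary,
                       fieldobj.flags, fieldobj.qlink, fieldobj.wall_u,
                       nx, ny, nz, px, py, pz)
    return fieldobj


def pressure_bc(fieldobj: LatticeField) -> LatticeField:
    """Re-impose the density boundary conditions on current populations."""
    if len(fieldobj._bc_nodes):
        lk.pressure_bc(fieldobj.f, fieldobj.rho, fieldobj.u,
                       fieldobj._bc_nodes, fieldobj._bc_nbr, fieldobj._bc_rho)
    return fieldobj
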