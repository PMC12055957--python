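"""Constricted and cross-slot microchannel geometries as lattice flag fields.

Both channels have square cross-sections of width ``l`` and rounded
corners:

* constricted: a 45-degree converging section feeding a narrow straight
  channel of width ``l`` (20 um in the experiments), junction corners
  rounded with radius 20 um; origin at the entry of the straight channel,
  x the flow axis, y the height, z lateral.
* cross-slot: four branches of width ``l`` (40 um) meeting at a junction
  whose corners are rounded with radius 10 um; origin at the cross centre;
  flow enters along +-x and leaves along +-z.

Nodes are cell-centred: physical position = origin + (index + 1/2) dx.
Wall links carry Bouzidi fractions q in [0, 1) obtained by bisection of the
inside/outside predicate along the link.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from numba import njit

from . import _lbm_kernels as lk
from .fluid_lbm import LatticeConfig, LatticeField
from .params import FluidModel

__all__ = ["ChannelGeometry", "build_constricted", "build_cross_slot",
           "build_straight", "boundary_links"]

_SQ2 = np.sqrt(2.0)


@njit(cache=True)
def _inside(kind, p, x, y, z):
    """Inside-fluid predicate.  kind 0: constricted, 1: cross-slot."""
    if kind == 0:
        l, half_h, r, x_min, x_max = p[0], p[1], p[2], p[3], p[4]
        if abs(y) >= half_h or x <= x_min or x >= x_max:
            return False
        xc = r * (_SQ2 - 1.0)
        xs = xc - r / _SQ2
        if x >= xc:
            w = 0.5 * l
        elif x >= xs:
            w = 0.5 * l + r - np.sqrt(r * r - (x - xc) * (x - xc))
        else:
            w = 0.5 * l - x
        return abs(z) < w
    if kind == 1:
        l, half_h, r = p[0], p[1], p[2]
        x_min, x_max, z_min, z_max = p[3], p[4], p[5], p[6]
        if abs(y) >= half_h:
            return False
        if x <= x_min or x >= x_max or z <= z_min or z >= z_max:
            return False
        ax = abs(x)
        az = abs(z)
        hl = 0.5 * l
        # inside either branch slab
        if az < hl or ax < hl:
            return True
        # rounded junction corners: fluid between corner tip and fillet arc
        if ax <= hl + r and az <= hl + r:
            dx_ = ax - (hl + r)
            dz_ = az - (hl + r)
            return dx_ * dx_ + dz_ * dz_ >= r * r
        return False
    # kind 2: plain straight square duct
    if kind == 2:
        l, half_h, x_min, x_max = p[0], p[1], p[2], p[3]
        return abs(y) < half_h and abs(z) < 0.5 * l and x_min < x < x_max
    return False


@njit(cache=True)
def _build_flags(kind, p, ox, oy, oz, dx, nx, ny, nz):
    flags = np.zeros((nx, ny, nz), dtype=np.uint8)
    for ix in range(nx):
        x = ox + (ix + 0.5) * dx
        for iy in range(ny):
            y = oy + (iy + 0.5) * dx
            for iz in range(nz):
                z = oz + (iz + 0.5) * dx
                if _inside(kind, p, x, y, z):
                    flags[ix, iy, iz] = 1
    return flags


@njit(cache=True)
def _qlink_build(kind, p, ox, oy, oz, dx, flags):
    """Per-link fluid fractions by bisection of the inside predicate."""
    nx, ny, nz = flags.shape
    N = nx * ny * nz
    q = np.full((N, 19), -1.0)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if flags[ix, iy, iz] == 0:
                    continue
                x0 = ox + (ix + 0.5) * dx
                y0 = oy + (iy + 0.5) * dx
                z0 = oz + (iz + 0.5) * dx
                n = (ix * ny + iy) * nz + iz
                for i in range(1, 19):
                    jx = ix + lk.C[i, 0]
                    jy = iy + lk.C[i, 1]
                    jz = iz + lk.C[i, 2]
                    if not (0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz):
                        continue
                    if flags[jx, jy, jz] != 0:
                        continue
                    ex = lk.C[i, 0] * dx
                    ey = lk.C[i, 1] * dx
                    ez = lk.C[i, 2] * dx
                    lo = 0.0
                    hi = 1.0
                    for _ in range(40):
                        mid = 0.5 * (lo + hi)
                        if _inside(kind, p,
                                   x0 + mid * ex, y0 + mid * ey, z0 + mid * ez):
                            lo = mid
                        else:
                            hi = mid
                    q[n, i] = 0.5 * (lo + hi)
    return q


@dataclass
class ChannelGeometry:
    """Flag field, Bouzidi fractions and boundary planes of one channel."""

    kind: str  # "constricted" | "cross_slot"
    l: float  # channel width (m)
    dx: float
    origin: np.ndarray  # physical position of the lower box corner (m)
    flags: np.ndarray  # (nx, ny, nz) uint8
    qlink: np.ndarray  # (N, 19)
    inlet_planes: list  # [(axis, side), ...]
    outlet_planes: list
    params: np.ndarray = dfield(default_factory=lambda: np.zeros(1))
    kind_id: int = 0

    @property
    def shape(self) -> tuple:
        return self.flags.shape

    def node_positions(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.dx

    def inside(self, x: float, y: float, z: float) -> bool:
        return bool(_inside(self.kind_id, self.params, x, y, z))

    def check_connectivity(self) -> None:
        from scipy import ndimage

        lab, nlab = ndimage.label(self.flags != 0)
        if nlab != 1:
            raise ValueError(f"fluid region split into {nlab} components")

    def make_field(self, config: LatticeConfig, dp: float = 0.0,
                   lam: float = 1.0) -> LatticeField:
        """Instantiate a lattice with pressure boundaries at +-dp/2 (Pa)."""
        if abs(config.dx - self.dx) > 1e-12 * self.dx:
            raise ValueError("lattice dx differs from geometry dx")
        fieldobj = LatticeField(self.flags, config, qlink=self.qlink,
                                origin=self.origin)
        drho = config.pressure_to_drho(dp)
        planes = [(ax, sd, 1.0 + drho / 2.0) for ax, sd in self.inlet_planes]
        planes += [(ax, sd, 1.0 - drho / 2.0) for ax, sd in self.outlet_planes]
        fieldobj.set_pressure_boundaries(planes)
        fieldobj.set_viscosity_ratio(lam)
        return fieldobj


def build_constricted(
    l: float = 20e-6,
    corner_r: float = 20e-6,
    straight_len: float = 400e-6,
    height: float | None = None,
    converging_len: float = 120e-6,
    nodes_per_l: int = 64,
) -> ChannelGeometry:
    """Constricted channel: 45-degree converging section + straight narrow
    channel of width ``l``; junction corners rounded with ``corner_r``.

    The computational domain spans x in [-converging_len, straight_len].
    """
    dx = l / nodes_per_l
    height = l if height is None else height
    x_min = -float(converging_len)
    x_max = float(straight_len)
    # box: width follows the widest section (at x_min), plus one solid layer
    w_max = 0.5 * l + converging_len
    nx = int(round((x_max - x_min) / dx))
    # three solid layers beyond each wall so the 4-point IBM stencil stays
    # inside the array even for a vertex lying on the wall itself
    ny = int(round(height / dx)) + 6
    nz = 2 * (int(np.ceil(w_max / dx)) + 3)
    origin = np.array([x_min, -0.5 * height - 3 * dx, -(nz // 2) * dx])
    p = np.array([l, 0.5 * height, corner_r, x_min, x_max])
    flags = _build_flags(0, p, origin[0], origin[1], origin[2], dx, nx, ny, nz)
    q = _qlink_build(0, p, origin[0], origin[1], origin[2], dx, flags)
    geo = ChannelGeometry(
        kind="constricted", l=l, dx=dx, origin=origin, flags=flags, qlink=q,
        inlet_planes=[(0, 0)], outlet_planes=[(0, -1)],
        params=p, kind_id=0,
    )
    geo.check_connectivity()
    return geo


def build_cross_slot(
    l: float = 40e-6,
    corner_r: float = 10e-6,
    feed_len: float = 440e-6,
    other_len: float = 160e-6,
    height: float | None = None,
    nodes_per_l: int = 64,
) -> ChannelGeometry:
    """Cross-slot: inflow branches along +-x, outflow along +-z.

    The feeding branch (inlet at x = -feed_len - l/2) is longer so a cell
    reaches its steady shape before entering the junction.
    """
    dx = l / nodes_per_l
    height = l if height is None else height
    x_min = -(feed_len + 0.5 * l)
    x_max = other_len + 0.5 * l
    z_min = -(other_len + 0.5 * l)
    z_max = other_len + 0.5 * l
    nx = int(round((x_max - x_min) / dx))
    ny = int(round(height / dx)) + 6
    nz = int(round((z_max - z_min) / dx))
    origin = np.array([x_min, -0.5 * height - 3 * dx, z_min])
    p = np.array([l, 0.5 * height, corner_r, x_min, x_max, z_min, z_max])
    flags = _build_flags(1, p, origin[0], origin[1], origin[2], dx, nx, ny, nz)
    q = _qlink_build(1, p, origin[0], origin[1], origin[2], dx, flags)
    geo = ChannelGeometry(
        kind="cross_slot", l=l, dx=dx, origin=origin, flags=flags, qlink=q,
        inlet_planes=[(0, 0), (0, -1)], outlet_planes=[(2, 0), (2, -1)],
        params=p, kind_id=1,
    )
    geo.check_connectivity()
    return geo


def build_straight(
    l: float = 20e-6,
    length: float = 160e-6,
    height: float | None = None,
    nodes_per_l: int = 16,
) -> ChannelGeometry:
    """Plain straight square duct (steady-shape libraries and solver tests)."""
    dx = l / nodes_per_l
    height = l if height is None else height
    nx = int(round(length / dx))
    ny = int(round(height / dx)) + 6
    nz = int(round(l / dx)) + 6
    origin = np.array([0.0, -0.5 * height - 3 * dx, -0.5 * l - 3 * dx])
    p = np.array([l, 0.5 * height, 0.0, length])
    flags = _build_flags(2, p, origin[0], origin[1], origin[2], dx, nx, ny, nz)
    q = _qlink_build(2, p, origin[0], origin[1], origin[2], dx, flags)
    geo = ChannelGeometry(
        kind="straight", l=l, dx=dx, origin=origin, flags=flags, qlink=q,
        inlet_planes=[(0, 0)], outlet_planes=[(0, -1)],
        params=p, kind_id=2,
    )
    geo.check_connectivity()
    return geo


def boundary_links(geometry: ChannelGeometry) -> np.ndarray:
    """(N, 19) Bouzidi fluid fractions (negative where the link is fluid)."""
    return geometry.qlink
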