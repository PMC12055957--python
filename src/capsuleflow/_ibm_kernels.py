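"""Numba kernels for immersed-boundary spreading/interpolation and the
front-tracking indicator construction.

The 4-point Peskin cosine-like kernel (phi supported on [-2, 2], exact
partition of unity and first moment on integer shifts) is used for both
force spreading and velocity interpolation, making the two operations
adjoint.  Lagrangian positions are in lattice coordinates (node n at
integer coordinates, physical position = (index + 1/2) dx).
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def peskin4(r):
    a = abs(r)
    if a >= 2.0:
        return 0.0
    if a <= 1.0:
        return 0.125 * (3.0 - 2.0 * a + np.sqrt(1.0 + 4.0 * a - 4.0 * a * a))
    return 0.125 * (5.0 - 2.0 * a - np.sqrt(-7.0 + 12.0 * a - 4.0 * a * a))


@njit(cache=True, fastmath=True)
def spread(positions, values, out, nx, ny, nz):
    """Spread Lagrangian ``values`` to the flat Eulerian field ``out`` (N, 3).

    Returns the number of markers whose 4^3 stencil was clipped by the
    domain boundary (should stay zero in valid runs).
    """
    clipped = 0
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    for m in range(positions.shape[0]):
        X = positions[m, 0]
        Y = positions[m, 1]
        Z = positions[m, 2]
        bx = int(np.floor(X)) - 1
        by = int(np.floor(Y)) - 1
        bz = int(np.floor(Z)) - 1
        if bx < 0 or by < 0 or bz < 0 or bx + 3 >= nx or by + 3 >= ny or bz + 3 >= nz:
            clipped += 1
        for t in range(4):
            wx[t] = peskin4(X - (bx + t))
            wy[t] = peskin4(Y - (by + t))
            wz[t] = peskin4(Z - (bz + t))
        vx = values[m, 0]
        vy = values[m, 1]
        vz = values[m, 2]
        for i in range(4):
            gx = bx + i
            if gx < 0 or gx >= nx:
                continue
            for j in range(4):
                gy = by + j
                if gy < 0 or gy >= ny:
                    continue
                wxy = wx[i] * wy[j]
                for k in range(4):
                    gz = bz + k
                    if gz < 0 or gz >= nz:
                        continue
                    w = wxy * wz[k]
                    n = (gx * ny + gy) * nz + gz
                    out[n, 0] += w * vx
                    out[n, 1] += w * vy
                    out[n, 2] += w * vz
    return clipped


@njit(cache=True, fastmath=True)
def interp(field, positions, out, nx, ny, nz):
    """Interpolate the flat Eulerian field (N, 3) at Lagrangian positions."""
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    for m in range(positions.shape[0]):
        X = positions[m, 0]
        Y = positions[m, 1]
        Z = positions[m, 2]
        bx = int(np.floor(X)) - 1
        by = int(np.floor(Y)) - 1
        bz = int(np.floor(Z)) - 1
        for t in range(4):
            wx[t] = peskin4(X - (bx + t))
            wy[t] = peskin4(Y - (by + t))
            wz[t] = peskin4(Z - (bz + t))
        sx = 0.0
        sy = 0.0
        sz = 0.0
        for i in range(4):
            gx = bx + i
            if gx < 0 or gx >= nx:
                continue
            for j in range(4):
                gy = by + j
                if gy < 0 or gy >= ny:
                    continue
                wxy = wx[i] * wy[j]
                for k in range(4):
                    gz = bz + k
                    if gz < 0 or gz >= nz:
                        continue
                    w = wxy * wz[k]
                    n = (gx * ny + gy) * nz + gz
                    sx += w * field[n, 0]
                    sy += w * field[n, 1]
                    sz += w * field[n, 2]
        out[m, 0] = sx
        out[m, 1] = sy
        out[m, 2] = sz


@njit(cache=True, fastmath=True)
def spread_scalar_box(positions, vectors, box_origin, G):
    """Spread Lagrangian vector densities into a (bx, by, bz, 3) sub-box."""
    nbx, nby, nbz = G.shape[0], G.shape[1], G.shape[2]
    wx = np.empty(4)
    wy = np.empty(4)
    wz = np.empty(4)
    ox, oy, oz = box_origin[0], box_origin[1], box_origin[2]
    for m in range(positions.shape[0]):
        X = positions[m, 0] - ox
        Y = positions[m, 1] - oy
        Z = positions[m, 2] - oz
        bx = int(np.floor(X)) - 1
        by = int(np.floor(Y)) - 1
        bz = int(np.floor(Z)) - 1
        for t in range(4):
            wx[t] = peskin4(X - (bx + t))
            wy[t] = peskin4(Y - (by + t))
            wz[t] = peskin4(Z - (bz + t))
        for i in range(4):
            gx = bx + i
            if gx < 0 or gx >= nbx:
                continue
            for j in range(4):
                gy = by + j
                if gy < 0 or gy >= nby:
                    continue
                wxy = wx[i] * wy[j]
                for k in range(4):
                    gz = bz + k
                    if gz < 0 or gz >= nbz:
                        continue
                    w = wxy * wz[k]
                    G[gx, gy, gz, 0] += w * vectors[m, 0]
                    G[gx, gy, gz, 1] += w * vectors[m, 1]
                    G[gx, gy, gz, 2] += w * vectors[m, 2]


@njit(cache=True)
def ray_cast_inside(points_yz, x_lo, x_hi, verts, tri, inside_x):
    """Crossing-parity point-in-mesh test along x-lines.

    For each (y, z) line, collect x-intersections with the mesh and mark
    ``inside_x[m, ix]`` for lattice x-indices between successive crossings.
    ``points_yz`` are (M, 2) lattice (y, z) line coordinates; x-indices run
    from x_lo to x_hi inclusive.
    """
    nxs = x_hi - x_lo + 1
    xs = np.empty(64)
    for m in range(points_yz.shape[0]):
        y = points_yz[m, 0]
        z = points_yz[m, 1]
        ncross = 0
        for e in range(tri.shape[0]):
            i0, i1, i2 = tri[e, 0], tri[e, 1], tri[e, 2]
            y0 = verts[i0, 1] - y
            z0 = verts[i0, 2] - z
            y1 = verts[i1, 1] - y
            z1 = verts[i1, 2] - z
            y2 = verts[i2, 1] - y
            z2 = verts[i2, 2] - z
            # does the triangle's yz projection contain the origin?
            d0 = y0 * z1 - y1 * z0
            d1 = y1 * z2 - y2 * z1
            d2 = y2 * z0 - y0 * z2
            has_neg = (d0 < 0.0) or (d1 < 0.0) or (d2 < 0.0)
            has_pos = (d0 > 0.0) or (d1 > 0.0) or (d2 > 0.0)
            if has_neg and has_pos:
                continue
            denom = d0 + d1 + d2
            if denom == 0.0:
                continue
            xx = (
                d1 * verts[i0, 0] + d2 * verts[i1, 0] + d0 * verts[i2, 0]
            ) / denom
            if ncross < 64:
                xs[ncross] = xx
                ncross += 1
        # sort the few crossings (insertion sort)
        for a in range(1, ncross):
            v = xs[a]
            b = a - 1
            while b >= 0 and xs[b] > v:
                xs[b + 1] = xs[b]
                b -= 1
            xs[b + 1] = v
        # mark inside intervals (pairs of crossings)
        for p in range(0, ncross - 1, 2):
            lo = xs[p]
            hi = xs[p + 1]
            ilo = int(np.ceil(lo - x_lo))
            ihi = int(np.floor(hi - x_lo))
            if ilo < 0:
                ilo = 0
            if ihi >= nxs:
                ihi = nxs - 1
            for ix in range(ilo, ihi + 1):
                inside_x[m, ix] = True
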