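"""Numba kernels for the D3Q19 lattice-Boltzmann solver.

BGK collision with Guo forcing; truncated power-law viscosity evaluated per
node from the shear rate reconstructed from non-equilibrium moments; Bouzidi
linear interpolated bounce-back at curved walls; Guo non-equilibrium
extrapolation for pressure (density) inlets/outlets.  All quantities in
lattice units (dx = dt = 1, cs^2 = 1/3, mean density 1).

Storage is flat: populations f[n, i] with n the C-ordered flat node index of
an (nx, ny, nz) box.  Streaming is split into a fast path over interior
nodes (all 19 upwind sources in-domain and non-solid, constant flat offsets)
and a general path over the remaining boundary nodes.

Flag values: 0 solid, 1 fluid, 2 inlet, 3 outlet.
"""

import numpy as np
from numba import njit

# D3Q19 velocity set: rest, 6 axis, 12 edge diagonals
C = np.array(
    [
        [0, 0, 0],
        [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
        [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
        [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1],
    ],
    dtype=np.int64,
)
CF = C.astype(np.float64)
W = np.array([1.0 / 3.0] + [1.0 / 18.0] * 6 + [1.0 / 36.0] * 12)
OPP = np.array(
    [0, 2, 1, 4, 3, 6, 5, 8, 7, 10, 9, 12, 11, 14, 13, 16, 15, 18, 17],
    dtype=np.int64,
)

SOLID, FLUID, INLET, OUTLET = 0, 1, 2, 3


@njit(cache=True, fastmath=True)
def equilibrium_node(rho, ux, uy, uz, feq):
    usq = ux * ux + uy * uy + uz * uz
    for i in range(19):
        cu = CF[i, 0] * ux + CF[i, 1] * uy + CF[i, 2] * uz
        feq[i] = W[i] * rho * (1.0 + 3.0 * cu + 4.5 * cu * cu - 1.5 * usq)


@njit(cache=True)
def init_equilibrium(f, nonsolid, rho0, u0):
    feq = np.empty(19)
    equilibrium_node(rho0, u0[0], u0[1], u0[2], feq)
    for k in range(nonsolid.shape[0]):
        n = nonsolid[k]
        for i in range(19):
            f[n, i] = feq[i]


@njit(cache=True, fastmath=True)
def collide(f, fpost, nonsolid, tau, force, Icell, Inuc,
            nu_K, alpha, gd_min, gd_max, inv_dt, nu_cyt, nu_nuc, gd_out,
            rho_out, u_out, update_visc):
    """Fused macroscopic / viscosity / BGK-Guo collision pass.

    Stores the pre-streaming (time-t) density and half-force-corrected
    velocity into ``rho_out``/``u_out``.  When ``update_visc`` is false the
    shear-rate reconstruction and relaxation-time update are skipped and the
    previous ``tau`` is reused (the viscosity field evolves on the flow time
    scale, far slower than one lattice step).
    """
    feq = np.empty(19)
    for k in range(nonsolid.shape[0]):
        n = nonsolid[k]
        rho = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        for i in range(19):
            fi = f[n, i]
            rho += fi
            mx += fi * CF[i, 0]
            my += fi * CF[i, 1]
            mz += fi * CF[i, 2]
        Fx = force[n, 0]
        Fy = force[n, 1]
        Fz = force[n, 2]
        ux = (mx + 0.5 * Fx) / rho
        uy = (my + 0.5 * Fy) / rho
        uz = (mz + 0.5 * Fz) / rho
        rho_out[n] = rho
        u_out[n, 0] = ux
        u_out[n, 1] = uy
        u_out[n, 2] = uz
        equilibrium_node(rho, ux, uy, uz, feq)
        if update_visc:
            pxx = 0.0
            pyy = 0.0
            pzz = 0.0
            pxy = 0.0
            pxz = 0.0
            pyz = 0.0
            for i in range(1, 19):
                fneq = f[n, i] - feq[i]
                cx = CF[i, 0]
                cy = CF[i, 1]
                cz = CF[i, 2]
                pxx += fneq * cx * cx
                pyy += fneq * cy * cy
                pzz += fneq * cz * cz
                pxy += fneq * cx * cy
                pxz += fneq * cx * cz
                pyz += fneq * cy * cz
            # Guo half-force correction to the non-equilibrium stress
            pxx += ux * Fx
            pyy += uy * Fy
            pzz += uz * Fz
            pxy += 0.5 * (ux * Fy + uy * Fx)
            pxz += 0.5 * (ux * Fz + uz * Fx)
            pyz += 0.5 * (uy * Fz + uz * Fy)
            tloc = tau[n]
            coef = -1.5 / (rho * tloc)
            sxx = coef * pxx
            syy = coef * pyy
            szz = coef * pzz
            sxy = coef * pxy
            sxz = coef * pxz
            syz = coef * pyz
            gd_lat = np.sqrt(
                2.0 * (sxx * sxx + syy * syy + szz * szz
                       + 2.0 * (sxy * sxy + sxz * sxz + syz * syz))
            )
            gd_phys = gd_lat * inv_dt
            gd_out[n] = gd_phys
            if gd_phys < gd_min:
                gd_phys = gd_min
            elif gd_phys > gd_max:
                gd_phys = gd_max
            nu_ext = nu_K * gd_phys ** (alpha - 1.0)
            ic = Icell[n]
            if ic < 0.0:
                ic = 0.0
            elif ic > 1.0:
                ic = 1.0
            inn = Inuc[n]
            if inn < 0.0:
                inn = 0.0
            elif inn > ic:
                inn = ic
            nu = nu_ext * (1.0 - ic) + nu_cyt * (ic - inn) + nu_nuc * inn
            tau[n] = 3.0 * nu + 0.5
        omega = 1.0 / tau[n]
        if Fx == 0.0 and Fy == 0.0 and Fz == 0.0:
            for i in range(19):
                fpost[n, i] = f[n, i] - omega * (f[n, i] - feq[i])
        else:
            fpref = 1.0 - 0.5 * omega
            for i in range(19):
                cx = CF[i, 0]
                cy = CF[i, 1]
                cz = CF[i, 2]
                cu = cx * ux + cy * uy + cz * uz
                guo = W[i] * (
                    3.0 * ((cx - ux) * Fx + (cy - uy) * Fy + (cz - uz) * Fz)
                    + 9.0 * cu * (cx * Fx + cy * Fy + cz * Fz)
                )
                fpost[n, i] = (
                    f[n, i] - omega * (f[n, i] - feq[i]) + fpref * guo
                )


@njit(cache=True, fastmath=True)
def stream_interior(f, fpost, interior, noff):
    """Pull streaming for nodes whose 19 upwind sources are all non-solid."""
    for k in range(interior.shape[0]):
        n = interior[k]
        f[n, 0] = fpost[n, 0]
        for i in range(1, 19):
            f[n, i] = fpost[n - noff[i], i]


@njit(cache=True)
def stream_boundary(f, fpost, bnodes, flags, qlink, wall_u,
                    nx, ny, nz, px, py, pz):
    """General pull streaming with Bouzidi bounce-back at wall links.

    ``flags`` is the flat flag array; ``qlink[n, j]`` the fluid fraction of
    the link from node n in direction j when that neighbour is solid.
    ``wall_u[n]`` is the wall velocity at solid node n (moving-wall tests).
    """
    nyz = ny * nz
    for k in range(bnodes.shape[0]):
        n = bnodes[k]
        ix = n // nyz
        iy = (n // nz) % ny
        iz = n % nz
        for i in range(19):
            sx = ix - C[i, 0]
            sy = iy - C[i, 1]
            sz = iz - C[i, 2]
            if px:
                sx = sx % nx
            if py:
                sy = sy % ny
            if pz:
                sz = sz % nz
            inb = 0 <= sx < nx and 0 <= sy < ny and 0 <= sz < nz
            if inb:
                ns = (sx * ny + sy) * nz + sz
                if flags[ns] != SOLID:
                    f[n, i] = fpost[ns, i]
                    continue
            else:
                # beyond an open boundary plane: hold (overwritten by the BC)
                f[n, i] = fpost[n, i]
                continue
            # wall link: Bouzidi linear interpolation
            j = OPP[i]
            q = qlink[n, j]
            if q < 0.0:
                q = 0.5
            fj = fpost[n, j]
            mw = 6.0 * W[j] * (
                C[j, 0] * wall_u[ns, 0]
                + C[j, 1] * wall_u[ns, 1]
                + C[j, 2] * wall_u[ns, 2]
            )
            if q < 0.5:
                tx = ix + C[i, 0]
                ty = iy + C[i, 1]
                tz = iz + C[i, 2]
                if px:
                    tx = tx % nx
                if py:
                    ty = ty % ny
                if pz:
                    tz = tz % nz
                if 0 <= tx < nx and 0 <= ty < ny and 0 <= tz < nz:
                    nt = (tx * ny + ty) * nz + tz
                    if flags[nt] != SOLID:
                        f[n, i] = (
                            2.0 * q * fj + (1.0 - 2.0 * q) * fpost[nt, j] + mw
                        )
                    else:
                        f[n, i] = fj + mw
                else:
                    f[n, i] = fj + mw
            else:
                f[n, i] = (
                    fj / (2.0 * q)
                    + (1.0 - 1.0 / (2.0 * q)) * fpost[n, i]
                    + mw / (2.0 * q)
                )


@njit(cache=True, fastmath=True)
def macros(f, nonsolid, force, rho, u):
    """Density and half-force-corrected velocity on non-solid nodes."""
    for k in range(nonsolid.shape[0]):
        n = nonsolid[k]
        r = 0.0
        mx = 0.0
        my = 0.0
        mz = 0.0
        for i in range(19):
            fi = f[n, i]
            r += fi
            mx += fi * CF[i, 0]
            my += fi * CF[i, 1]
            mz += fi * CF[i, 2]
        rho[n] = r
        u[n, 0] = (mx + 0.5 * force[n, 0]) / r
        u[n, 1] = (my + 0.5 * force[n, 1]) / r
        u[n, 2] = (mz + 0.5 * force[n, 2]) / r


@njit(cache=True)
def pressure_bc(f, rho, u, bc_nodes, bc_nbr, bc_rho):
    """Guo non-equilibrium extrapolation at inlet/outlet nodes.

    f_i(b) = feq_i(rho_target, u_n) + (f_i(n) - feq_i(rho_n, u_n)) with n the
    interior neighbour of boundary node b.
    """
    feq_b = np.empty(19)
    feq_n = np.empty(19)
    for k in range(bc_nodes.shape[0]):
        b = bc_nodes[k]
        n = bc_nbr[k]
        ux = u[n, 0]
        uy = u[n, 1]
        uz = u[n, 2]
        equilibrium_node(bc_rho[k], ux, uy, uz, feq_b)
        equilibrium_node(rho[n], ux, uy, uz, feq_n)
        for i in range(19):
            f[b, i] = feq_b[i] + (f[n, i] - feq_n[i])
        rho[b] = bc_rho[k]
        u[b, 0] = ux
        u[b, 1] = uy
        u[b, 2] = uz


@njit(cache=True)
def total_mass(f, nonsolid):
    m = 0.0
    for k in range(nonsolid.shape[0]):
        n = nonsolid[k]
        for i in range(19):
            m += f[n, i]
    return m


@njit(cache=True)
def build_boundary_tables(bnodes, flags, qlink, wall_u, nx, ny, nz,
                          px, py, pz):
    """Precompute per-link streaming actions for boundary nodes.

    mode 0: copy population i from source node srcA;
    mode 1: hold (open-boundary link, overwritten by the pressure BC);
    mode 2: plain bounce-back  f_i = fpost_j(n) + mw;
    mode 3: Bouzidi q < 1/2    f_i = cA fpost_j(n) + cB fpost_j(srcA) + mw;
    mode 4: Bouzidi q >= 1/2   f_i = cA fpost_j(n) + cB fpost_i(n) + mw.
    """
    nb = bnodes.shape[0]
    mode = np.empty((nb, 19), dtype=np.uint8)
    srcA = np.empty((nb, 19), dtype=np.int64)
    cA = np.zeros((nb, 19))
    cB = np.zeros((nb, 19))
    mw = np.zeros((nb, 19))
    nyz = ny * nz
    for k in range(nb):
        n = bnodes[k]
        ix = n // nyz
        iy = (n // nz) % ny
        iz = n % nz
        mode[k, 0] = 0
        srcA[k, 0] = n
        for i in range(1, 19):
            sx = ix - C[i, 0]
            sy = iy - C[i, 1]
            sz = iz - C[i, 2]
            if px:
                sx = sx % nx
            if py:
                sy = sy % ny
            if pz:
                sz = sz % nz
            inb = 0 <= sx < nx and 0 <= sy < ny and 0 <= sz < nz
            if inb:
                ns = (sx * ny + sy) * nz + sz
                if flags[ns] != SOLID:
                    mode[k, i] = 0
                    srcA[k, i] = ns
                    continue
            else:
                mode[k, i] = 1
                srcA[k, i] = n
                continue
            j = OPP[i]
            q = qlink[n, j]
            if q < 0.0:
                q = 0.5
            mwv = 6.0 * W[j] * (
                CF[j, 0] * wall_u[ns, 0]
                + CF[j, 1] * wall_u[ns, 1]
                + CF[j, 2] * wall_u[ns, 2]
            )
            if q < 0.5:
                tx = ix + C[i, 0]
                ty = iy + C[i, 1]
                tz = iz + C[i, 2]
                if px:
                    tx = tx % nx
                if py:
                    ty = ty % ny
                if pz:
                    tz = tz % nz
                nt = -1
                if 0 <= tx < nx and 0 <= ty < ny and 0 <= tz < nz:
                    ntc = (tx * ny + ty) * nz + tz
                    if flags[ntc] != SOLID:
                        nt = ntc
                if nt >= 0:
                    mode[k, i] = 3
                    srcA[k, i] = nt
                    cA[k, i] = 2.0 * q
                    cB[k, i] = 1.0 - 2.0 * q
                    mw[k, i] = mwv
                else:
                    mode[k, i] = 2
                    srcA[k, i] = n
                    mw[k, i] = mwv
            else:
                mode[k, i] = 4
                srcA[k, i] = n
                cA[k, i] = 1.0 / (2.0 * q)
                cB[k, i] = 1.0 - 1.0 / (2.0 * q)
                mw[k, i] = mwv / (2.0 * q)
    return mode, srcA, cA, cB, mw


@njit(cache=True, fastmath=True)
def stream_boundary_tab(f, fpost, bnodes, mode, srcA, cA, cB, mw):
    """Table-driven boundary streaming (see build_boundary_tables)."""
    for k in range(bnodes.shape[0]):
        n = bnodes[k]
        f[n, 0] = fpost[n, 0]
        for i in range(1, 19):
            m = mode[k, i]
            if m == 0:
                f[n, i] = fpost[srcA[k, i], i]
            elif m == 1:
                f[n, i] = fpost[n, i]
            else:
                j = OPP[i]
                if m == 2:
                    f[n, i] = fpost[n, j] + mw[k, i]
                elif m == 3:
                    f[n, i] = (cA[k, i] * fpost[n, j]
                               + cB[k, i] * fpost[srcA[k, i], j] + mw[k, i])
                else:
                    f[n, i] = (cA[k, i] * fpost[n, j]
                               + cB[k, i] * fpost[n, i] + mw[k, i])
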