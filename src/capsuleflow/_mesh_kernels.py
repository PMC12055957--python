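"""Numba kernels for triangulated-membrane geometry and mechanics.

Per-element membrane kinematics use the constant-strain-triangle map: each
flat triangle carries a 2x2 in-plane deformation gradient F from its
stress-free reference shape, giving principal stretches (lambda1, lambda2)
from the left Cauchy-Green tensor B = F F^T.  In-plane membrane tensions
(elastic Skalak + viscous) are converted to nodal forces with the
virtual-work assembly f_a = -A tau grad(N_a), which has exactly vanishing
resultant force and torque per element.

Curvature uses the cotangent Laplace-Beltrami mean-curvature vector with
barycentric vertex areas; bending nodal forces are the negative gradient of
the discrete Helfrich energy, evaluated by central finite differences
localised to the 1-ring of the perturbed vertex.
"""

import numpy as np
from numba import njit

_EPS = 1.0e-300


@njit(cache=True, fastmath=False)
def tri_geometry(x, tri):
    """Per-triangle area, unit normal and centroid."""
    nf = tri.shape[0]
    area = np.empty(nf)
    normal = np.empty((nf, 3))
    cent = np.empty((nf, 3))
    for e in range(nf):
        i0, i1, i2 = tri[e, 0], tri[e, 1], tri[e, 2]
        ax = x[i1, 0] - x[i0, 0]
        ay = x[i1, 1] - x[i0, 1]
        az = x[i1, 2] - x[i0, 2]
        bx = x[i2, 0] - x[i0, 0]
        by = x[i2, 1] - x[i0, 1]
        bz = x[i2, 2] - x[i0, 2]
        nx = ay * bz - az * by
        ny = az * bx - ax * bz
        nz = ax * by - ay * bx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        area[e] = 0.5 * nn
        inv = 1.0 / (nn + _EPS)
        normal[e, 0] = nx * inv
        normal[e, 1] = ny * inv
        normal[e, 2] = nz * inv
        for k in range(3):
            cent[e, k] = (x[i0, k] + x[i1, k] + x[i2, k]) / 3.0
    return area, normal, cent


@njit(cache=True)
def enclosed_volume(x, tri):
    """Signed volume by the divergence theorem (positive for outward winding)."""
    vol = 0.0
    for e in range(tri.shape[0]):
        i0, i1, i2 = tri[e, 0], tri[e, 1], tri[e, 2]
        vol += (
            x[i0, 0] * (x[i1, 1] * x[i2, 2] - x[i1, 2] * x[i2, 1])
            - x[i0, 1] * (x[i1, 0] * x[i2, 2] - x[i1, 2] * x[i2, 0])
            + x[i0, 2] * (x[i1, 0] * x[i2, 1] - x[i1, 1] * x[i2, 0])
        )
    return vol / 6.0


@njit(cache=True)
def _local2d(x0, x1, x2):
    """Orthonormal in-plane frame and 2D coordinates of a triangle.

    Returns (e1, e2, (a1, a2, b2)) where vertex0 -> (0,0),
    vertex1 -> (a1, 0), vertex2 -> (a2, b2).
    """
    d1 = x1 - x0
    d2 = x2 - x0
    a1 = np.sqrt(d1[0] ** 2 + d1[1] ** 2 + d1[2] ** 2)
    e1 = d1 / (a1 + _EPS)
    nx = d1[1] * d2[2] - d1[2] * d2[1]
    ny = d1[2] * d2[0] - d1[0] * d2[2]
    nz = d1[0] * d2[1] - d1[1] * d2[0]
    nn = np.sqrt(nx * nx + ny * ny + nz * nz) + _EPS
    n = np.empty(3)
    n[0] = nx / nn
    n[1] = ny / nn
    n[2] = nz / nn
    e2 = np.empty(3)
    e2[0] = n[1] * e1[2] - n[2] * e1[1]
    e2[1] = n[2] * e1[0] - n[0] * e1[2]
    e2[2] = n[0] * e1[1] - n[1] * e1[0]
    a2 = d2[0] * e1[0] + d2[1] * e1[1] + d2[2] * e1[2]
    b2 = d2[0] * e2[0] + d2[1] * e2[1] + d2[2] * e2[2]
    return e1, e2, a1, a2, b2


@njit(cache=True)
def reference_shape(xref, tri):
    """Per-element inverse reference-shape matrix and reference area.

    ``Dm_inv[e]`` maps reference 2D edge coordinates to barycentric-gradient
    space: F = Ds @ Dm_inv with Ds the current 2D edge matrix.
    """
    nf = tri.shape[0]
    Dm_inv = np.empty((nf, 2, 2))
    area0 = np.empty(nf)
    for e in range(nf):
        x0 = xref[tri[e, 0]]
        x1 = xref[tri[e, 1]]
        x2 = xref[tri[e, 2]]
        _, _, a1, a2, b2 = _local2d(x0, x1, x2)
        det = a1 * b2
        if det <= 0.0:
            raise ValueError("degenerate reference element")
        area0[e] = 0.5 * det
        # Dm = [[a1, a2], [0, b2]]; inverse:
        Dm_inv[e, 0, 0] = 1.0 / a1
        Dm_inv[e, 0, 1] = -a2 / det
        Dm_inv[e, 1, 0] = 0.0
        Dm_inv[e, 1, 1] = a1 / det
    return Dm_inv, area0


@njit(cache=True)
def _sym_eig2(a, b, c):
    """Eigen-decomposition of [[a, b], [b, c]]: returns (l1, l2, cos, sin).

    l1 >= l2; eigenvector of l1 is (cos, sin).
    """
    tr = a + c
    diff = a - c
    disc = np.sqrt(diff * diff + 4.0 * b * b)
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    if disc < 1.0e-30 * (abs(tr) + 1.0e-300):
        return l1, l2, 1.0, 0.0
    # (a - l1) vx + b vy = 0
    if abs(b) > 1.0e-300:
        vx = b
        vy = l1 - a
    else:
        if a >= c:
            vx, vy = 1.0, 0.0
        else:
            vx, vy = 0.0, 1.0
    nn = np.sqrt(vx * vx + vy * vy) + _EPS
    return l1, l2, vx / nn, vy / nn


@njit(cache=True)
def sk_principal_stresses(l1, l2, Gs, C):
    """Skalak-law principal tensions tau1, tau2 (N/m) from stretches."""
    I1 = l1 * l1 + l2 * l2 - 2.0
    I2 = (l1 * l2) ** 2 - 1.0
    t1 = Gs * l1 / l2 * (I1 + 1.0 - l2 * l2) + C * Gs * I2 * l1 * l2
    t2 = Gs * l2 / l1 * (I1 + 1.0 - l1 * l1) + C * Gs * I2 * l1 * l2
    return t1, t2


@njit(cache=True)
def membrane_forces(x, x_prev, tri, Dm_inv, area0, dt, Gs, C, mu_s, mu_s_dil,
                    forces, lam_out, tau_out, D_out):
    """Elastic + viscous in-plane nodal forces (accumulated into ``forces``).

    Per element: deformation gradient F (reference -> current, 2x2 in the
    current in-plane frame), stretches from B = F F^T, Skalak principal
    tensions rotated back to tensor form, plus the viscous tension from the
    relative deformation rate D = sym((F_rel - I)/dt) with F_rel the
    previous->current in-plane map.  Nodal forces f_a = -A_cur * tau @ gradN_a.

    Outputs: ``lam_out[e] = (lambda1, lambda2)``, ``tau_out[e]`` total 2x2
    tension in the element frame, ``D_out[e]`` 2x2 strain rate.
    Returns the total elastic energy (J).
    """
    nf = tri.shape[0]
    energy = 0.0
    for e in range(nf):
        i0, i1, i2 = tri[e, 0], tri[e, 1], tri[e, 2]
        e1, e2, a1, a2, b2 = _local2d(x[i0], x[i1], x[i2])
        if a1 * b2 <= 0.0:
            raise ValueError("degenerate current element")
        # current 2D edge matrix Ds = [[a1, a2], [0, b2]]
        # F = Ds @ Dm_inv
        F00 = a1 * Dm_inv[e, 0, 0] + a2 * Dm_inv[e, 1, 0]
        F01 = a1 * Dm_inv[e, 0, 1] + a2 * Dm_inv[e, 1, 1]
        F10 = b2 * Dm_inv[e, 1, 0]
        F11 = b2 * Dm_inv[e, 1, 1]
        # B = F F^T (current-frame left Cauchy-Green)
        B00 = F00 * F00 + F01 * F01
        B01 = F00 * F10 + F01 * F11
        B11 = F10 * F10 + F11 * F11
        b1sq, b2sq, cx, sx = _sym_eig2(B00, B01, B11)
        if b2sq <= 0.0:
            raise ValueError("non-positive stretch")
        l1 = np.sqrt(b1sq)
        l2 = np.sqrt(b2sq)
        lam_out[e, 0] = l1
        lam_out[e, 1] = l2
        t1, t2 = sk_principal_stresses(l1, l2, Gs, C)
        # tension tensor in the element frame: R diag(t1,t2) R^T
        T00 = t1 * cx * cx + t2 * sx * sx
        T01 = (t1 - t2) * cx * sx
        T11 = t1 * sx * sx + t2 * cx * cx
        I1 = l1 * l1 + l2 * l2 - 2.0
        I2 = (l1 * l2) ** 2 - 1.0
        W = 0.25 * Gs * (I1 * I1 + 2.0 * I1 - 2.0 * I2) + 0.25 * C * Gs * I2 * I2
        energy += W * area0[e]

        # viscous tension from previous->current relative map
        D00 = 0.0
        D01 = 0.0
        D11 = 0.0
        if dt > 0.0 and (mu_s > 0.0 or mu_s_dil > 0.0):
            p0 = x_prev[i0]
            p1 = x_prev[i1]
            p2 = x_prev[i2]
            _, _, pa1, pa2, pb2 = _local2d(p0, p1, p2)
            detp = pa1 * pb2
            if detp > 0.0:
                # Dm_prev_inv
                P00 = 1.0 / pa1
                P01 = -pa2 / detp
                P11 = pa1 / detp
                # F_rel = Ds_cur @ Dm_prev_inv
                R00 = a1 * P00
                R01 = a1 * P01 + a2 * P11
                R10 = 0.0
                R11 = b2 * P11
                L00 = (R00 - 1.0) / dt
                L01 = R01 / dt
                L10 = R10 / dt
                L11 = (R11 - 1.0) / dt
                D00 = L00
                D01 = 0.5 * (L01 + L10)
                D11 = L11
                trD = D00 + D11
                T00 += mu_s * (2.0 * D00 - trD) + mu_s_dil * trD
                T01 += mu_s * 2.0 * D01
                T11 += mu_s * (2.0 * D11 - trD) + mu_s_dil * trD
        D_out[e, 0, 0] = D00
        D_out[e, 0, 1] = D01
        D_out[e, 1, 0] = D01
        D_out[e, 1, 1] = D11
        tau_out[e, 0, 0] = T00
        tau_out[e, 0, 1] = T01
        tau_out[e, 1, 0] = T01
        tau_out[e, 1, 1] = T11

        # shape-function gradients in the current frame
        # vertices at (0,0), (a1,0), (a2,b2); area Acur = a1*b2/2
        Acur = 0.5 * a1 * b2
        inv2A = 1.0 / (2.0 * Acur)
        # gradN in 2D: N0: ((y1-y2)... use standard formula with local coords
        # P0=(0,0), P1=(a1,0), P2=(a2,b2)
        g0x = (0.0 - b2) * inv2A
        g0y = (a2 - a1) * inv2A
        g1x = b2 * inv2A
        g1y = -a2 * inv2A
        g2x = 0.0
        g2y = a1 * inv2A
        # nodal force (2D) f_a = -Acur * T @ gradN_a
        for a_i in range(3):
            if a_i == 0:
                gx, gy, idx = g0x, g0y, i0
            elif a_i == 1:
                gx, gy, idx = g1x, g1y, i1
            else:
                gx, gy, idx = g2x, g2y, i2
            fx2 = -Acur * (T00 * gx + T01 * gy)
            fy2 = -Acur * (T01 * gx + T11 * gy)
            forces[idx, 0] += fx2 * e1[0] + fy2 * e2[0]
            forces[idx, 1] += fx2 * e1[1] + fy2 * e2[1]
            forces[idx, 2] += fx2 * e1[2] + fy2 * e2[2]
    return energy


@njit(cache=True)
def element_deformation(x, xref, tri, Dm_inv):
    """Principal stretches and 3D principal directions per element."""
    nf = tri.shape[0]
    lam = np.empty((nf, 2))
    dir1 = np.empty((nf, 3))
    dir2 = np.empty((nf, 3))
    for e in range(nf):
        i0, i1, i2 = tri[e, 0], tri[e, 1], tri[e, 2]
        e1, e2, a1, a2, b2 = _local2d(x[i0], x[i1], x[i2])
        if a1 * b2 <= 0.0:
            raise ValueError("degenerate current element")
        F00 = a1 * Dm_inv[e, 0, 0] + a2 * Dm_inv[e, 1, 0]
        F01 = a1 * Dm_inv[e, 0, 1] + a2 * Dm_inv[e, 1, 1]
        F10 = b2 * Dm_inv[e, 1, 0]
        F11 = b2 * Dm_inv[e, 1, 1]
        B00 = F00 * F00 + F01 * F01
        B01 = F00 * F10 + F01 * F11
        B11 = F10 * F10 + F11 * F11
        b1sq, b2sq, cx, sx = _sym_eig2(B00, B01, B11)
        lam[e, 0] = np.sqrt(max(b1sq, 0.0))
        lam[e, 1] = np.sqrt(max(b2sq, 0.0))
        for k in range(3):
            dir1[e, k] = cx * e1[k] + sx * e2[k]
            dir2[e, k] = -sx * e1[k] + cx * e2[k]
    return lam, dir1, dir2


# ---------------------------------------------------------------------------
# curvature and bending
# ---------------------------------------------------------------------------


@njit(cache=True)
def vertex_curvature(x, tri, v2t_idx, v2t_ptr, H_out, A_out):
    """Cotangent-Laplacian mean curvature and barycentric vertex areas.

    ``H_out[v]`` is signed positive for a sphere with outward-oriented
    triangles.  ``v2t`` is CSR vertex->incident-triangle adjacency.
    """
    nv = x.shape[0]
    for v in range(nv):
        kx = 0.0
        ky = 0.0
        kz = 0.0
        av = 0.0
        nxs = 0.0
        nys = 0.0
        nzs = 0.0
        for p in range(v2t_ptr[v], v2t_ptr[v + 1]):
            t = v2t_idx[p]
            i0, i1, i2 = tri[t, 0], tri[t, 1], tri[t, 2]
            # rotate so that the first vertex is v
            if i0 == v:
                a, b, c = i0, i1, i2
            elif i1 == v:
                a, b, c = i1, i2, i0
            else:
                a, b, c = i2, i0, i1
            # triangle (v=a, b, c); angles at b and c are opposite to the
            # edges (a,c) and (a,b) respectively
            abx = x[b, 0] - x[a, 0]
            aby = x[b, 1] - x[a, 1]
            abz = x[b, 2] - x[a, 2]
            acx = x[c, 0] - x[a, 0]
            acy = x[c, 1] - x[a, 1]
            acz = x[c, 2] - x[a, 2]
            bcx = x[c, 0] - x[b, 0]
            bcy = x[c, 1] - x[b, 1]
            bcz = x[c, 2] - x[b, 2]
            # normal (outward if winding consistent)
            nx = aby * acz - abz * acy
            ny = abz * acx - abx * acz
            nz = abx * acy - aby * acx
            dbl_area = np.sqrt(nx * nx + ny * ny + nz * nz) + _EPS
            nxs += nx
            nys += ny
            nzs += nz
            av += dbl_area / 6.0  # barycentric third of the triangle area
            # cot at b (between BA and BC): BA = -ab, BC = bc
            dot_b = (-abx) * bcx + (-aby) * bcy + (-abz) * bcz
            cot_b = dot_b / dbl_area
            # cot at c (between CA and CB): CA = -ac, CB = -bc
            dot_c = (-acx) * (-bcx) + (-acy) * (-bcy) + (-acz) * (-bcz)
            cot_c = dot_c / dbl_area
            # edge (a, c) opposite b; edge (a, b) opposite c
            kx += cot_b * (x[a, 0] - x[c, 0]) + cot_c * (x[a, 0] - x[b, 0])
            ky += cot_b * (x[a, 1] - x[c, 1]) + cot_c * (x[a, 1] - x[b, 1])
            kz += cot_b * (x[a, 2] - x[c, 2]) + cot_c * (x[a, 2] - x[b, 2])
        # mean-curvature vector K = (1/(2A)) sum cot (x_v - x_j) = 2 H n_out
        kx *= 0.5 / av
        ky *= 0.5 / av
        kz *= 0.5 / av
        hmag = 0.5 * np.sqrt(kx * kx + ky * ky + kz * kz)
        sgn = kx * nxs + ky * nys + kz * nzs
        if sgn < 0.0:
            hmag = -hmag
        H_out[v] = hmag
        A_out[v] = av


@njit(cache=True)
def _local_bending_energy(x, tri, v2t_idx, v2t_ptr, verts, kc, c0):
    """Helfrich energy contribution of the listed vertices."""
    etot = 0.0
    for m in range(verts.shape[0]):
        v = verts[m]
        kx = 0.0
        ky = 0.0
        kz = 0.0
        av = 0.0
        nxs = 0.0
        nys = 0.0
        nzs = 0.0
        for p in range(v2t_ptr[v], v2t_ptr[v + 1]):
            t = v2t_idx[p]
            i0, i1, i2 = tri[t, 0], tri[t, 1], tri[t, 2]
            if i0 == v:
                a, b, c = i0, i1, i2
            elif i1 == v:
                a, b, c = i1, i2, i0
            else:
                a, b, c = i2, i0, i1
            abx = x[b, 0] - x[a, 0]
            aby = x[b, 1] - x[a, 1]
            abz = x[b, 2] - x[a, 2]
            acx = x[c, 0] - x[a, 0]
            acy = x[c, 1] - x[a, 1]
            acz = x[c, 2] - x[a, 2]
            bcx = x[c, 0] - x[b, 0]
            bcy = x[c, 1] - x[b, 1]
            bcz = x[c, 2] - x[b, 2]
            nx = aby * acz - abz * acy
            ny = abz * acx - abx * acz
            nz = abx * acy - aby * acx
            dbl_area = np.sqrt(nx * nx + ny * ny + nz * nz) + _EPS
            nxs += nx
            nys += ny
            nzs += nz
            av += dbl_area / 6.0
            dot_b = (-abx) * bcx + (-aby) * bcy + (-abz) * bcz
            cot_b = dot_b / dbl_area
            dot_c = (-acx) * (-bcx) + (-acy) * (-bcy) + (-acz) * (-bcz)
            cot_c = dot_c / dbl_area
            kx += cot_b * (x[a, 0] - x[c, 0]) + cot_c * (x[a, 0] - x[b, 0])
            ky += cot_b * (x[a, 1] - x[c, 1]) + cot_c * (x[a, 1] - x[b, 1])
            kz += cot_b * (x[a, 2] - x[c, 2]) + cot_c * (x[a, 2] - x[b, 2])
        kx *= 0.5 / av
        ky *= 0.5 / av
        kz *= 0.5 / av
        hmag = 0.5 * np.sqrt(kx * kx + ky * ky + kz * kz)
        sgn = kx * nxs + ky * nys + kz * nzs
        if sgn < 0.0:
            hmag = -hmag
        d = 2.0 * hmag - c0
        etot += 0.5 * kc * d * d * av
    return etot


@njit(cache=True)
def bending_energy(x, tri, v2t_idx, v2t_ptr, kc, c0):
    nv = x.shape[0]
    allv = np.arange(nv)
    return _local_bending_energy(x, tri, v2t_idx, v2t_ptr, allv, kc, c0)


@njit(cache=True)
def bending_forces_fd(x, tri, v2t_idx, v2t_ptr, ring_idx, ring_ptr, kc, c0, h,
                      forces):
    """Bending nodal forces as -grad of the discrete Helfrich energy.

    Central finite differences; moving vertex v only changes the energy terms
    of v and its 1-ring (``ring_idx/ring_ptr`` CSR, ring includes v itself).
    """
    nv = x.shape[0]
    xw = x.copy()
    for v in range(nv):
        verts = ring_idx[ring_ptr[v]:ring_ptr[v + 1]]
        for k in range(3):
            x0 = xw[v, k]
            xw[v, k] = x0 + h
            ep = _local_bending_energy(xw, tri, v2t_idx, v2t_ptr, verts, kc, c0)
            xw[v, k] = x0 - h
            em = _local_bending_energy(xw, tri, v2t_idx, v2t_ptr, verts, kc, c0)
            xw[v, k] = x0
            forces[v, k] -= (ep - em) / (2.0 * h)
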