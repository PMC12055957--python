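"""Membrane constitutive laws and nodal force densities.

The membrane tension is the sum of an elastic part from the strain-hardening
Skalak law,

    W = Gs/4 (I1^2 + 2 I1 - 2 I2) + C Gs/4 I2^2,
    tau1_e = (1/lambda2) dW/dlambda1,   tau2_e = (1/lambda1) dW/dlambda2,

and a viscous part from the in-plane strain rate,

    tau_v = mu_s (2 D - tr(D) P) + mu_s_dil tr(D) P,

with the dilatational viscosity neglected by default.  Bending resistance is
the Helfrich energy E_b = kc/2 \\int (2H - c0)^2 dA; its nodal forces are the
negative gradient of the discrete energy (cotangent-Laplacian curvature,
barycentric vertex areas), evaluated by ring-localised central differences.
In-plane tensions are assembled into nodal forces by virtual work on
constant-strain triangles, which makes the resultant force and torque of
every element vanish identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _mesh_kernels as mk
from .params import CellParams
from .surface_mesh import TriMesh, ElementKinematics, element_kinematics

__all__ = [
    "MembraneState",
    "Membrane",
    "sk_stresses",
    "strain_energy",
    "viscous_stress",
    "bending_forces",
    "nodal_forces",
]


def sk_stresses(lambda1, lambda2, Gs: float, C: float):
    """Skalak principal tensions (tau1, tau2) in N/m.

    Closed form:  tau1 = Gs (l1/l2) (I1 + 1 - l2^2) + C Gs I2 l1 l2
    and symmetrically for tau2.
    """
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("principal stretches must be positive")
    I1 = l1**2 + l2**2 - 2.0
    I2 = (l1 * l2) ** 2 - 1.0
    t1 = Gs * l1 / l2 * (I1 + 1.0 - l2**2) + C * Gs * I2 * l1 * l2
    t2 = Gs * l2 / l1 * (I1 + 1.0 - l1**2) + C * Gs * I2 * l1 * l2
    if np.ndim(lambda1) == 0 and np.ndim(lambda2) == 0:
        return float(t1), float(t2)
    return t1, t2


def strain_energy(lambda1, lambda2, Gs: float, C: float):
    """Skalak strain energy density W (N/m)."""
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    if np.any(l1 <= 0) or np.any(l2 <= 0):
        raise ValueError("principal stretches must be positive")
    I1 = l1**2 + l2**2 - 2.0
    I2 = (l1 * l2) ** 2 - 1.0
    W = 0.25 * Gs * (I1**2 + 2.0 * I1 - 2.0 * I2) + 0.25 * C * Gs * I2**2
    return float(W) if np.ndim(lambda1) == 0 and np.ndim(lambda2) == 0 else W


def viscous_stress(D, P=None, mu_s: float = 0.0, mu_s_dil: float = 0.0):
    """Viscous membrane tension tau_v = mu_s (2D - tr(D) P) + mu_s_dil tr(D) P.

    ``D`` is the symmetric in-plane strain-rate tensor (2x2 in the element
    frame, or an (..., 2, 2) stack); ``P`` defaults to the in-plane identity.
    """
    D = np.asarray(D, dtype=float)
    if not np.allclose(D, np.swapaxes(D, -1, -2), rtol=1e-10, atol=0.0):
        raise ValueError("strain-rate tensor must be symmetric")
    if P is None:
        P = np.broadcast_to(np.eye(D.shape[-1]), D.shape)
    trD = np.trace(D, axis1=-2, axis2=-1)[..., None, None]
    return mu_s * (2.0 * D - trD * P) + mu_s_dil * trD * P


def bending_forces(mesh: TriMesh, kc: float, c0: float = 0.0):
    """Helfrich bending energy (J) and per-vertex bending forces (N).

    Forces are the negative gradient of the discrete energy with respect to
    vertex positions (ring-localised central differences).
    """
    v2t_idx, v2t_ptr = mesh.vertex_triangle_adjacency()
    ring_idx, ring_ptr = mesh.vertex_ring()
    Eb = mk.bending_energy(mesh.vertices, mesh.triangles, v2t_idx, v2t_ptr, kc, c0)
    forces = np.zeros_like(mesh.vertices)
    if kc != 0.0:
        edge = np.linalg.norm(
            mesh.vertices[mesh.triangles[:, 1]] - mesh.vertices[mesh.triangles[:, 0]],
            axis=1,
        ).mean()
        h = 1.0e-6 * edge
        mk.bending_forces_fd(
            mesh.vertices, mesh.triangles, v2t_idx, v2t_ptr,
            ring_idx, ring_ptr, kc, c0, h, forces,
        )
    return float(Eb), forces


@dataclass
class MembraneState:
    """Stresses, energies and nodal forces of one membrane at one instant."""

    kinematics: ElementKinematics
    tau: np.ndarray  # (F, 2, 2) total in-plane tension, element frame (N/m)
    W: np.ndarray  # (F,) elastic energy density (N/m)
    elastic_energy: float  # J
    bending_energy: float  # J
    nodal_forces: np.ndarray  # (V, 3) N

    @property
    def dissipation_density(self) -> np.ndarray:
        """Per-element viscous dissipation tau_v : D >= 0 (W/m^2 * m = W/m?)."""
        D = self.kinematics.D
        return np.einsum("eij,eij->e", self.tau, D)


def nodal_forces(
    mesh: TriMesh,
    cell: CellParams | None = None,
    *,
    Gs: float | None = None,
    C: float | None = None,
    mu_s: float = 0.0,
    mu_s_dil: float = 0.0,
    kc: float | None = None,
    c0: float = 0.0,
    previous_vertices: np.ndarray | None = None,
    dt: float = 0.0,
) -> MembraneState:
    """Assemble total (elastic + viscous + bending) nodal forces.

    Either a :class:`CellParams` or explicit moduli must be given.  The
    viscous contribution needs the previous vertex configuration and ``dt``.
    """
    if cell is not None:
        Gs = cell.Gs if Gs is None else Gs
        C = cell.C if C is None else C
        mu_s = cell.mu_s
        mu_s_dil = cell.mu_s_dil
        kc = cell.kc if kc is None else kc
        c0 = cell.c0
    if Gs is None or C is None:
        raise ValueError("membrane moduli required")
    kc = 0.0 if kc is None else kc

    Dm_inv, area0 = mesh.reference_shape()
    nf = mesh.n_faces
    forces = np.zeros_like(mesh.vertices)
    lam = np.empty((nf, 2))
    tau = np.empty((nf, 2, 2))
    D = np.zeros((nf, 2, 2))
    xprev = (
        mesh.vertices
        if previous_vertices is None
        else np.ascontiguousarray(previous_vertices, dtype=float)
    )
    eff_dt = dt if previous_vertices is not None else 0.0
    elastic = mk.membrane_forces(
        mesh.vertices, xprev, mesh.triangles, Dm_inv, area0, eff_dt,
        Gs, C, mu_s, mu_s_dil, forces, lam, tau, D,
    )
    Eb, fb = bending_forces(mesh, kc, c0)
    forces += fb

    _, normals, _ = mk.tri_geometry(mesh.vertices, mesh.triangles)
    lam_ref, d1, d2 = mk.element_deformation(
        mesh.vertices, mesh.reference_vertices, mesh.triangles, Dm_inv
    )
    kin = ElementKinematics(
        lambda1=lam[:, 0], lambda2=lam[:, 1], e1=d1, e2=d2, D=D, normals=normals
    )
    W = strain_energy(lam[:, 0], lam[:, 1], Gs, C)
    return MembraneState(
        kinematics=kin,
        tau=tau,
        W=np.asarray(W),
        elastic_energy=float(elastic),
        bending_energy=Eb,
        nodal_forces=forces,
    )


class Membrane:
    """A closed membrane with its constitutive parameters, as stepped by the
    transit solver.  Keeps the previous configuration for the strain rate."""

    def __init__(
        self,
        mesh: TriMesh,
        Gs: float,
        C: float,
        mu_s: float = 0.0,
        mu_s_dil: float = 0.0,
        kc: float = 0.0,
        c0: float = 0.0,
    ):
        self.mesh = mesh
        self.Gs = Gs
        self.C = C
        self.mu_s = mu_s
        self.mu_s_dil = mu_s_dil
        self.kc = kc
        self.c0 = c0
        self.prev_vertices = mesh.vertices.copy()
        # pre-build caches so the stepping loop never re-derives topology
        mesh.reference_shape()
        mesh.vertex_triangle_adjacency()
        mesh.vertex_ring()
        self._fd_h = 1.0e-6 * float(
            np.linalg.norm(
                mesh.reference_vertices[mesh.triangles[:, 1]]
                - mesh.reference_vertices[mesh.triangles[:, 0]],
                axis=1,
            ).mean()
        )

    def forces(self, dt: float) -> np.ndarray:
        """Total nodal forces (N) for the current configuration."""
        mesh = self.mesh
        Dm_inv, area0 = mesh.reference_shape()
        nf = mesh.n_faces
        f = np.zeros_like(mesh.vertices)
        lam = np.empty((nf, 2))
        tau = np.empty((nf, 2, 2))
        D = np.zeros((nf, 2, 2))
        mk.membrane_forces(
            mesh.vertices, self.prev_vertices, mesh.triangles, Dm_inv, area0,
            dt if self.mu_s > 0 or self.mu_s_dil > 0 else 0.0,
            self.Gs, self.C, self.mu_s, self.mu_s_dil, f, lam, tau, D,
        )
        if self.kc != 0.0:
            v2t_idx, v2t_ptr = mesh.vertex_triangle_adjacency()
            ring_idx, ring_ptr = mesh.vertex_ring()
            mk.bending_forces_fd(
                mesh.vertices, mesh.triangles, v2t_idx, v2t_ptr,
                ring_idx, ring_ptr, self.kc, self.c0, self._fd_h, f,
            )
        return f

    def advance(self) -> None:
        """Snapshot the current configuration as 'previous' for the next step."""
        np.copyto(self.prev_vertices, self.mesh.vertices)

    def volume(self) -> float:
        return mk.enclosed_volume(self.mesh.vertices, self.mesh.triangles)
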