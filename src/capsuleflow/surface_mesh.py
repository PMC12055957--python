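"""Closed triangulated spherical meshes and per-element membrane kinematics.

Cell and nucleus membranes are closed genus-0 triangulations generated by
recursive 1->4 subdivision of a regular octahedron with projection of new
vertices onto the sphere, so that n subdivisions give F = 8 * 4**n faces and
V = F/2 + 2 vertices (n = 5 gives the production 8192 faces / 4098 nodes).
Each mesh carries its stress-free reference configuration; deformation is
measured per flat element through the in-plane deformation gradient against
that reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _mesh_kernels as mk

__all__ = [
    "TriMesh",
    "ElementKinematics",
    "make_sphere_mesh",
    "mesh_measures",
    "element_kinematics",
]


@dataclass
class TriMesh:
    """Closed, consistently outward-wound triangle mesh with a reference state.

    Attributes
    ----------
    vertices : (V, 3) float array
        Current vertex positions (m).
    triangles : (F, 3) int array
        Vertex index triplets, outward winding.
    reference_vertices : (V, 3) float array
        Stress-free positions (m).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    reference_vertices: np.ndarray | None = None

    # lazily built caches
    _v2t: tuple | None = field(default=None, repr=False)
    _ring: tuple | None = field(default=None, repr=False)
    _ref_shape: tuple | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.reference_vertices is None:
            self.reference_vertices = self.vertices.copy()
        else:
            self.reference_vertices = np.ascontiguousarray(
                self.reference_vertices, dtype=float
            )
        self.validate()

    # --- topology ---------------------------------------------------------
    def validate(self) -> None:
        """Closed-manifold checks: every edge shared by exactly two triangles,
        Euler characteristic 2, positive triangle areas."""
        tri = self.triangles
        if tri.min() < 0 or tri.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")
        edges = np.sort(
            np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1
        )
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise ValueError("mesh is not closed: edges not shared by two triangles")
        V, E, F = len(self.vertices), len(uniq), len(tri)
        if V - E + F != 2:
            raise ValueError(f"Euler characteristic {V - E + F} != 2 (genus 0 required)")
        area, _, _ = mk.tri_geometry(self.vertices, tri)
        if np.any(area <= 0):
            raise ValueError("zero-area triangle present")
        # consistent winding: each directed edge must appear exactly once
        directed = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        duniq = np.unique(directed, axis=0)
        if len(duniq) != len(directed):
            raise ValueError("inconsistent triangle winding")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.triangles)

    @property
    def n_edges(self) -> int:
        return 3 * self.n_faces // 2

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    # --- cached adjacency ---------------------------------------------------
    def vertex_triangle_adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR vertex -> incident triangles (idx, ptr)."""
        if self._v2t is None:
            tri = self.triangles
            counts = np.bincount(tri.ravel(), minlength=self.n_vertices)
            ptr = np.zeros(self.n_vertices + 1, dtype=np.int64)
            np.cumsum(counts, out=ptr[1:])
            idx = np.empty(3 * self.n_faces, dtype=np.int64)
            fill = ptr[:-1].copy()
            for t in range(self.n_faces):
                for v in tri[t]:
                    idx[fill[v]] = t
                    fill[v] += 1
            self._v2t = (idx, ptr)
        return self._v2t

    def vertex_ring(self) -> tuple[np.ndarray, np.ndarray]:
        """CSR vertex -> {itself + 1-ring neighbours} (idx, ptr)."""
        if self._ring is None:
            tri = self.triangles
            nbr = [set() for _ in range(self.n_vertices)]
            for a, b, c in tri:
                nbr[a].update((a, b, c))
                nbr[b].update((a, b, c))
                nbr[c].update((a, b, c))
            ptr = np.zeros(self.n_vertices + 1, dtype=np.int64)
            lists = [sorted(s) for s in nbr]
            ptr[1:] = np.cumsum([len(s) for s in lists])
            idx = np.fromiter(
                (v for s in lists for v in s), dtype=np.int64, count=ptr[-1]
            )
            self._ring = (idx, ptr)
        return self._ring

    def reference_shape(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-element inverse reference-shape matrices and reference areas."""
        if self._ref_shape is None:
            self._ref_shape = mk.reference_shape(
                self.reference_vertices, self.triangles
            )
        return self._ref_shape

    def copy(self) -> "TriMesh":
        m = TriMesh(
            self.vertices.copy(), self.triangles, self.reference_vertices.copy()
        )
        m._v2t = self._v2t
        m._ring = self._ring
        m._ref_shape = self._ref_shape
        return m


@dataclass
class ElementKinematics:
    """Per-element in-plane kinematics against the reference configuration."""

    lambda1: np.ndarray  # (F,) major principal stretch
    lambda2: np.ndarray  # (F,) minor principal stretch
    e1: np.ndarray  # (F, 3) major principal direction (current config)
    e2: np.ndarray  # (F, 3) minor principal direction
    D: np.ndarray  # (F, 2, 2) in-plane strain-rate tensor (1/s)
    normals: np.ndarray  # (F, 3) current unit normals

    @property
    def I1(self) -> np.ndarray:
        return self.lambda1**2 + self.lambda2**2 - 2.0

    @property
    def I2(self) -> np.ndarray:
        return (self.lambda1 * self.lambda2) ** 2 - 1.0

    @property
    def trD(self) -> np.ndarray:
        return self.D[:, 0, 0] + self.D[:, 1, 1]

    @property
    def P(self) -> np.ndarray:
        """(F, 3, 3) surface projection tensors I - n n^T."""
        n = self.normals
        return np.eye(3)[None] - n[:, :, None] * n[:, None, :]


def make_sphere_mesh(
    subdivisions: int, radius: float = 1.0, center=(0.0, 0.0, 0.0)
) -> TriMesh:
    """Octahedron-seeded subdivision sphere.

    ``subdivisions = n`` gives ``8 * 4**n`` faces and ``4**n * 4 + 2``
    vertices; n = 5 reproduces the production counts 8192 / 4098.
    """
    if subdivisions < 0 or int(subdivisions) != subdivisions:
        raise ValueError("subdivisions must be a non-negative integer")
    verts = np.array(
        [
            [1.0, 0, 0],
            [-1.0, 0, 0],
            [0, 1.0, 0],
            [0, -1.0, 0],
            [0, 0, 1.0],
            [0, 0, -1.0],
        ]
    )
    # outward-wound faces of the regular octahedron
    faces = np.array(
        [
            [0, 2, 4],
            [2, 1, 4],
            [1, 3, 4],
            [3, 0, 4],
            [2, 0, 5],
            [1, 2, 5],
            [3, 1, 5],
            [0, 3, 5],
        ],
        dtype=np.int64,
    )
    for _ in range(int(subdivisions)):
        verts, faces = _subdivide_project(verts, faces)
    verts = verts * float(radius) + np.asarray(center, dtype=float)
    return TriMesh(verts, faces)


def _subdivide_project(verts: np.ndarray, faces: np.ndarray):
    """One 1->4 subdivision step, new vertices projected to the unit sphere."""
    cache: dict[tuple[int, int], int] = {}
    vlist = list(map(tuple, verts))

    def midpoint(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        k = cache.get(key)
        if k is None:
            m = 0.5 * (np.asarray(vlist[i]) + np.asarray(vlist[j]))
            m /= np.linalg.norm(m)
            k = len(vlist)
            vlist.append(tuple(m))
            cache[key] = k
        return k

    new_faces = np.empty((4 * len(faces), 3), dtype=np.int64)
    for t, (a, b, c) in enumerate(faces):
        ab = midpoint(a, b)
        bc = midpoint(b, c)
        ca = midpoint(c, a)
        new_faces[4 * t + 0] = (a, ab, ca)
        new_faces[4 * t + 1] = (b, bc, ab)
        new_faces[4 * t + 2] = (c, ca, bc)
        new_faces[4 * t + 3] = (ab, bc, ca)
    return np.asarray(vlist, dtype=float), new_faces


def mesh_measures(mesh: TriMesh) -> tuple[float, float, np.ndarray]:
    """(total area, enclosed volume, per-vertex mean curvature).

    Volume is signed by the divergence theorem (positive for outward
    orientation); mean curvature comes from the cotangent Laplace-Beltrami
    operator with barycentric vertex areas, signed positive for a sphere
    with outward normals (H = 1/a).
    """
    area, _, _ = mk.tri_geometry(mesh.vertices, mesh.triangles)
    vol = mk.enclosed_volume(mesh.vertices, mesh.triangles)
    idx, ptr = mesh.vertex_triangle_adjacency()
    H = np.empty(mesh.n_vertices)
    A = np.empty(mesh.n_vertices)
    mk.vertex_curvature(mesh.vertices, mesh.triangles, idx, ptr, H, A)
    return float(area.sum()), float(vol), H


def element_kinematics(
    mesh: TriMesh, previous_vertices: np.ndarray | None = None, dt: float = 0.0
) -> ElementKinematics:
    """Per-element principal stretches/directions and in-plane strain rate.

    Stretches come from the affine map reference -> current triangle; the
    strain rate D from the relative map previous -> current configuration
    over ``dt`` (zero if no previous configuration is given).
    """
    Dm_inv, area0 = mesh.reference_shape()
    lam, d1, d2 = mk.element_deformation(mesh.vertices, mesh.reference_vertices,
                                         mesh.triangles, Dm_inv)
    nf = mesh.n_faces
    D = np.zeros((nf, 2, 2))
    if previous_vertices is not None:
        if dt <= 0:
            raise ValueError("dt must be positive when previous vertices are given")
        forces = np.zeros_like(mesh.vertices)
        lam_o = np.empty((nf, 2))
        tau_o = np.empty((nf, 2, 2))
        mk.membrane_forces(
            mesh.vertices, np.ascontiguousarray(previous_vertices, dtype=float),
            mesh.triangles, Dm_inv, area0, dt, 0.0, 0.0, 1.0, 0.0,
            forces, lam_o, tau_o, D,
        )
    _, normals, _ = mk.tri_geometry(mesh.vertices, mesh.triangles)
    return ElementKinematics(
        lambda1=lam[:, 0], lambda2=lam[:, 1], e1=d1, e2=d2, D=D, normals=normals
    )
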