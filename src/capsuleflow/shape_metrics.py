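"""Deformability-cytometry shape metrics on x-z cell contours.

* deformation index   DI = 1 - 2 sqrt(pi A) / P   (0 for a circle),
  computed on the convex hull of the projected membrane vertices;
* Taylor parameter    D_XZ = (a3 - a1) / (a3 + a1) from the maximum
  extents a3 (flow axis, x) and a1 (lateral, z);
* directed mean Hausdorff distance between centroid-aligned contours,
  the objective used to select the best-fitting steady shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "ContourProfile",
    "project_xz",
    "deformation_index",
    "taylor_parameter",
    "mean_hausdorff",
    "resample_contour",
]


@dataclass
class ContourProfile:
    """Closed planar contour as an ordered (N, 2) polyline of (x, z) points."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("contour needs an (N>=3, 2) point array")
        self.points = pts

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.linalg.norm(d, axis=1).sum())

    @property
    def area(self) -> float:
        """Signed shoelace area, returned positive."""
        x, z = self.points[:, 0], self.points[:, 1]
        return float(abs(np.dot(x, np.roll(z, -1)) - np.dot(z, np.roll(x, -1))) / 2.0)

    @property
    def extents(self) -> tuple[float, float]:
        """(a1, a3): maximum dimensions along x and z respectively."""
        span = self.points.max(axis=0) - self.points.min(axis=0)
        return float(span[0]), float(span[1])


def project_xz(mesh) -> ContourProfile:
    """Convex hull of the mesh vertices projected onto the x-z plane."""
    pts = np.asarray(mesh.vertices if hasattr(mesh, "vertices") else mesh, dtype=float)
    xz = pts[:, [0, 2]] if pts.shape[1] == 3 else pts
    uniq = np.unique(xz, axis=0)
    if len(uniq) < 3:
        raise ValueError("fewer than 3 distinct projected points")
    hull = ConvexHull(xz)
    return ContourProfile(xz[hull.vertices])


def deformation_index(contour: ContourProfile) -> float:
    """DI = 1 - 2 sqrt(pi A) / P; zero iff the contour is a circle."""
    P = contour.perimeter
    if P <= 0:
        raise ValueError("zero-perimeter contour")
    return float(1.0 - 2.0 * np.sqrt(np.pi * contour.area) / P)


def taylor_parameter(contour: ContourProfile) -> float:
    """D_XZ = (a3 - a1)/(a3 + a1) with a1 the x-extent and a3 the z-extent.

    In the cross-slot the outflow (elongation) axis is z, so a cell
    stretched by the extensional flow has positive D_XZ.
    """
    a1, a3 = contour.extents
    if a3 + a1 <= 0:
        raise ValueError("degenerate contour extents")
    return float((a3 - a1) / (a3 + a1))


def resample_contour(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` points at equal arc-length spacing."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("contour has zero length")
    si = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(si, s, closed[:, 0])
    z = np.interp(si, s, closed[:, 1])
    return np.column_stack([x, z])


def mean_hausdorff(
    R: ContourProfile | np.ndarray,
    S: ContourProfile | np.ndarray,
    resample: int | None = 512,
    align: bool = True,
) -> float:
    """Directed mean Hausdorff distance h(R, S) = mean_r min_s |r - s|.

    ``R`` is the simulated contour, ``S`` the observed one.  Both point sets
    are centroid-aligned first (the two profiles are assumed to share their
    centre of mass) and, for closed contours, resampled to equal arc-length
    spacing.  Directed: h(R, S) != h(S, R) in general.
    """
    r = R.points if isinstance(R, ContourProfile) else np.asarray(R, dtype=float)
    s = S.points if isinstance(S, ContourProfile) else np.asarray(S, dtype=float)
    if len(r) == 0 or len(s) == 0:
        raise ValueError("empty point set")
    if resample is not None:
        r = resample_contour(r, resample)
        s = resample_contour(s, resample)
    if align:
        r = r - r.mean(axis=0)
        s = s - s.mean(axis=0)
    d, _ = cKDTree(s).query(r)
    return float(d.mean())
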