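"""File I/O: contour CSV series, legacy-VTK/PLY export, HDF5 checkpoints.

Contour CSV layout (header required):

    frame,t,point_index,x_um,z_um

with ``t`` either time (s) or any strictly increasing frame coordinate.
"""

from __future__ import annotations

import json
import hashlib
import os

import numpy as np
import pandas as pd

__all__ = [
    "write_contours",
    "read_contours",
    "write_vtk_polydata",
    "write_vtk_structured",
    "write_ply",
    "save_checkpoint",
    "load_checkpoint",
    "provenance_header",
]

_CONTOUR_COLUMNS = ["frame", "t", "point_index", "x_um", "z_um"]


def write_contours(path, contours, times) -> None:
    """Write a contour series ((k_i, 2) arrays in um) to CSV."""
    rows = []
    for frame, (t, pts) in enumerate(zip(times, contours)):
        pts = np.asarray(pts, dtype=float)
        for j, (x, z) in enumerate(pts):
            rows.append((frame, t, j, x, z))
    df = pd.DataFrame(rows, columns=_CONTOUR_COLUMNS)
    df.to_csv(path, index=False)


def read_contours(path):
    """Read a contour series; returns (times, [contour arrays in um]).

    Malformed rows are reported with their line numbers; the frame times
    must be strictly increasing.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contour CSV missing header columns {missing}")
    bad_lines = []
    values = {}
    for col in _CONTOUR_COLUMNS:
        v = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(v.isna().to_numpy())
        # +2: header line and 1-based numbering
        bad_lines.extend((int(b) + 2) for b in bad)
        values[col] = v
    if bad_lines:
        raise ValueError(
            f"non-numeric contour rows at line(s) {sorted(set(bad_lines))}"
        )
    num = pd.DataFrame(values)
    times = []
    contours = []
    for frame, grp in num.groupby("frame", sort=True):
        grp = grp.sort_values("point_index")
        times.append(float(grp.t.iloc[0]))
        contours.append(grp[["x_um", "z_um"]].to_numpy())
    times = np.asarray(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    return times, contours


# --- mesh / field export ----------------------------------------------------

def write_vtk_polydata(path, vertices, triangles, point_data=None,
                       cell_data=None) -> None:
    """Legacy-ASCII VTK polydata export of a triangle mesh."""
    vertices = np.asarray(vertices, dtype=float)
    triangles = np.asarray(triangles, dtype=np.int64)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncapsuleflow mesh\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} double\n")
        for v in vertices:
            fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
        fh.write(f"POLYGONS {len(triangles)} {4 * len(triangles)}\n")
        for t in triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {len(vertices)}\n")
            _write_vtk_attributes(fh, point_data)
        if cell_data:
            fh.write(f"CELL_DATA {len(triangles)}\n")
            _write_vtk_attributes(fh, cell_data)


def _write_vtk_attributes(fh, data: dict) -> None:
    for name, arr in data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for v in arr:
                fh.write(f"{v:.9e}\n")
        else:
            fh.write(f"VECTORS {name} double\n")
            for v in arr:
                fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")


def write_vtk_structured(path, origin, dx, fields: dict) -> None:
    """Legacy-ASCII VTK structured-points export of lattice fields."""
    first = next(iter(fields.values()))
    nx, ny, nz = first.shape[:3]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncapsuleflow field\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.9e} {origin[1]:.9e} {origin[2]:.9e}\n")
        fh.write(f"SPACING {dx:.9e} {dx:.9e} {dx:.9e}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            arr = np.asarray(arr, dtype=float)
            # VTK structured points expect x fastest: transpose from C order
            if arr.ndim == 3:
                flat = arr.transpose(2, 1, 0).reshape(-1)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in flat:
                    fh.write(f"{v:.9e}\n")
            else:
                flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
                fh.write(f"VECTORS {name} double\n")
                for v in flat:
                    fh.write(f"{v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")


def write_ply(path, mesh) -> None:
    """PLY export through trimesh."""
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                         process=False)
    tm.export(path)


def save_checkpoint(path, field) -> None:
    """HDF5 checkpoint of a lattice field."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["dx"] = field.config.dx
        h5.attrs["dt"] = field.config.dt
        h5.attrs["steps"] = field.steps
        h5.attrs["time"] = field.time
        for name in ("f", "tau", "rho", "u", "Icell", "Inuc", "force"):
            h5.create_dataset(name, data=getattr(field, name),
                              compression="gzip", compression_opts=1)


def load_checkpoint(path, field) -> None:
    import h5py

    with h5py.File(path, "r") as h5:
        for name in ("f", "tau", "rho", "u", "Icell", "Inuc", "force"):
            getattr(field, name)[:] = h5[name][...]
        field.steps = int(h5.attrs["steps"])
        field.time = float(h5.attrs["time"])
    field.refresh_macros()


def provenance_header(config: dict, seed: int | None = None) -> dict:
    """Provenance block attached to every output (config hash, version)."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "code_version": __version__,
        "config_sha1": hashlib.sha1(blob).hexdigest(),
        "seed": seed,
    }
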