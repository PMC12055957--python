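"""Full cell-transit simulations: pressure calibration, compound-cell
initialisation, explicit time stepping and trajectory recording.

A transit couples one lattice-Boltzmann fluid, one viscoelastic cell
membrane and one hyperelastic nucleus membrane through the immersed
boundary.  The global explicit time step is bounded by the membrane
stiffness criterion

    dt <= dt_safety * mu0 * dx / (Gs (1 + 2C))

and by the lattice compressibility limit; all components advance with the
same dt.  There are no stochastic elements: reruns are bitwise stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dfield

import numpy as np

from . import _cache
from .channel_geometry import ChannelGeometry, build_constricted, \
    build_cross_slot, build_straight
from .coupling_ibm import spread_forces, interpolate_velocity, update_indicator
from .fluid_lbm import LatticeConfig, LatticeField
from .membrane_mechanics import Membrane
from .params import DimensionlessGroups, FluidModel
from .shape_metrics import ContourProfile, deformation_index, project_xz, \
    taylor_parameter
from .surface_mesh import make_sphere_mesh

__all__ = ["TransitConfig", "TrajectoryRecord", "calibrate_pressure",
           "run_transit", "residence_time"]


@dataclass
class TransitConfig:
    """All parameters of one transit run (SI units; groups dimensionless)."""

    kind: str  # "constricted" | "cross_slot"
    fluid: FluidModel
    groups: DimensionlessGroups
    U: float  # mean branch speed (m/s)
    l: float  # channel width (m)
    nodes_per_l: int = 16
    mesh_subdivisions: int = 3
    d_oc_y: float = 0.0  # initial offsets, fractions of l
    d_oc_z: float = 0.0
    release_x: float | None = None  # m; geometry-dependent default
    # geometry lengths (m); defaults follow the experimental chips but can be
    # shortened for reduced-scale runs
    straight_len: float = 400e-6
    converging_len: float = 120e-6
    feed_len: float = 440e-6
    other_len: float = 160e-6
    corner_r: float | None = None
    dt_safety: float = 0.1
    u_lat_max: float = 0.1
    visc_every: int = 5
    indicator_every: int = 10
    strain_window: int | None = None  # steps between strain-rate baselines
    record_every: int = 50  # steps between trajectory samples
    max_tstar: float = 20.0
    steady_dDI: float = 1.0e-3  # per l of travel (constricted termination)
    lam: float = 1.0
    use_cache: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("constricted", "cross_slot", "straight"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if abs(self.d_oc_y) > 0.1 or abs(self.d_oc_z) > 0.1:
            raise ValueError("initial offsets must stay below 0.1 l")
        if self.corner_r is None:
            self.corner_r = 20e-6 if self.kind == "constricted" else 10e-6
        if self.kind == "straight":
            self.converging_len = 0.0

    # --- derived cell parameters -----------------------------------------
    @property
    def a(self) -> float:
        return 0.5 * self.groups.confinement * self.l

    @property
    def Gs(self) -> float:
        return self.fluid.mu0 * self.U / self.groups.Ca

    @property
    def Ks(self) -> float:
        return (1.0 + 2.0 * self.groups.C) * self.Gs

    @property
    def mu_s(self) -> float:
        return self.groups.eta * self.fluid.mu0 * self.a

    @property
    def kc(self) -> float:
        return 0.001 * self.Gs * self.a**2

    @property
    def dt(self) -> float:
        dx = self.l / self.nodes_per_l
        dt_mem = self.dt_safety * self.fluid.mu0 * dx / (
            self.Gs * (1.0 + 2.0 * self.groups.C)
        )
        dt_comp = self.u_lat_max * dx / (2.5 * self.U)
        return min(dt_mem, dt_comp)

    @property
    def target_Q(self) -> float:
        return self.U * self.l**2

    def strain_window_steps(self) -> int:
        """Baseline length (steps) for the membrane strain rate.

        The viscous membrane tension is explicit; evaluating the strain rate
        by differencing configurations ``k`` steps apart removes the
        grid-frequency feedback that makes large membrane viscosities stiff,
        while the baseline k*dt stays far below the flow time scale l/U.
        """
        if self.strain_window is not None:
            return self.strain_window
        if self.mu_s == 0.0:
            return 1
        dx = self.l / self.nodes_per_l
        r = self.mu_s * self.dt / (self.fluid.rho * dx**3)
        return max(1, int(np.ceil(r)))

    def geometry(self) -> ChannelGeometry:
        if self.kind == "constricted":
            return build_constricted(
                l=self.l, corner_r=self.corner_r,
                straight_len=self.straight_len,
                converging_len=self.converging_len,
                nodes_per_l=self.nodes_per_l,
            )
        if self.kind == "straight":
            return build_straight(l=self.l, length=self.straight_len,
                                  nodes_per_l=self.nodes_per_l)
        return build_cross_slot(
            l=self.l, corner_r=self.corner_r, feed_len=self.feed_len,
            other_len=self.other_len, nodes_per_l=self.nodes_per_l,
        )

    def lattice_config(self) -> LatticeConfig:
        return LatticeConfig(dx=self.l / self.nodes_per_l, dt=self.dt,
                             fluid=self.fluid)

    def default_release_x(self) -> float:
        if self.release_x is not None:
            return self.release_x
        if self.kind == "constricted":
            return -60e-6
        if self.kind == "straight":
            return self.a + 6 * self.l / self.nodes_per_l
        # start of the feeding branch, one radius + kernel margin inside
        return -(self.feed_len + 0.5 * self.l) + self.a + 5 * self.l / self.nodes_per_l

    def _flow_key(self) -> dict:
        return {
            "kind": self.kind, "l": self.l, "U": self.U,
            "nodes_per_l": self.nodes_per_l, "dt": self.dt,
            "lam": self.lam, "corner_r": self.corner_r,
            "straight_len": self.straight_len,
            "converging_len": self.converging_len,
            "feed_len": self.feed_len, "other_len": self.other_len,
            "fluid": [self.fluid.K, self.fluid.alpha, self.fluid.gamma0,
                      self.fluid.gamma_min, self.fluid.gamma_max,
                      self.fluid.rho, self.fluid.mu0],
        }


@dataclass
class TrajectoryRecord:
    """Time series of one transit."""

    t: np.ndarray  # s
    tstar: np.ndarray  # t / (l/U)
    centroid: np.ndarray  # (n, 3) m
    DI: np.ndarray
    DXZ: np.ndarray
    vol_cell: np.ndarray  # m^3
    vol_nucleus: np.ndarray
    contours: list  # (k, 2) x-z polylines, um
    events: dict = dfield(default_factory=dict)
    meta: dict = dfield(default_factory=dict)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "tstar": self.tstar,
            "x": self.centroid[:, 0], "y": self.centroid[:, 1],
            "z": self.centroid[:, 2],
            "DI": self.DI, "DXZ": self.DXZ,
            "vol_cell": self.vol_cell, "vol_nucleus": self.vol_nucleus,
        })

    @property
    def volume_drift(self) -> float:
        """Largest relative enclosed-volume drift of either membrane."""
        dc = np.abs(self.vol_cell / self.vol_cell[0] - 1.0).max()
        dn = np.abs(self.vol_nucleus / self.vol_nucleus[0] - 1.0).max()
        return float(max(dc, dn))


def calibrate_pressure(geometry: ChannelGeometry, config: LatticeConfig,
                       target_Q: float, lam: float = 1.0,
                       tol: float = 0.005, max_iter: int = 20,
                       field_out: list | None = None) -> float:
    """Pressure difference (Pa) whose cell-free steady flow rate matches
    ``target_Q`` within ``tol`` (secant iteration on dp).

    If ``field_out`` is given, the converged cell-free lattice field is
    appended to it (used to warm-start transits).
    """
    if target_Q == 0.0:
        return 0.0
    # measurement plane: inside the feed/straight branch
    axis = 0
    index = 4
    mu = config.fluid.mu0
    l = geometry.l

    def measure(fieldobj: LatticeField) -> float:
        prev = None
        for _ in range(40):
            fieldobj.step(400)
            q = fieldobj.flow_rate(axis=axis, index=index)
            if prev is not None and abs(q - prev) <= 1.0e-3 * abs(q):
                break
            prev = q
        return q

    # initial guess from a square-duct estimate over the domain length
    L_tot = geometry.shape[0] * geometry.dx
    dp1 = 28.4 * mu * target_Q / l**4 * L_tot / 2.0
    fieldobj = geometry.make_field(config, dp=dp1, lam=lam)
    fieldobj.visc_every = 5
    Q1 = measure(fieldobj)
    dp = dp1
    Q = Q1
    dp_prev, Q_prev = 0.0, 0.0
    for it in range(max_iter):
        if abs(Q - target_Q) <= tol * target_Q:
            if field_out is not None:
                field_out.append(fieldobj)
            return dp
        if it == 0 or Q == Q_prev:
            dp_new = dp * target_Q / Q
        else:
            dp_new = dp + (target_Q - Q) * (dp - dp_prev) / (Q - Q_prev)
        dp_prev, Q_prev = dp, Q
        dp = dp_new
        drho = config.pressure_to_drho(dp)
        planes = [(ax, sd, 1.0 + drho / 2.0) for ax, sd in geometry.inlet_planes]
        planes += [(ax, sd, 1.0 - drho / 2.0) for ax, sd in geometry.outlet_planes]
        fieldobj.set_pressure_boundaries(planes)
        Q = measure(fieldobj)
    raise RuntimeError(
        f"pressure calibration did not converge in {max_iter} iterations"
    )


def _steady_flow(config_t: TransitConfig, geometry: ChannelGeometry):
    """Cell-free calibrated steady flow (dp and populations), cached."""
    key = {"what": "steady_flow", "shape": list(geometry.shape),
           **config_t._flow_key()}
    if config_t.use_cache:
        hit = _cache.load(key)
        if hit is not None:
            return float(hit["dp"]), hit["f"]
    out: list = []
    dp = calibrate_pressure(geometry, config_t.lattice_config(),
                            config_t.target_Q, lam=config_t.lam,
                            field_out=out)
    fieldobj = out[0]
    if config_t.use_cache:
        _cache.save(key, {"dp": np.float64(dp), "f": fieldobj.f})
    return dp, fieldobj.f


def run_transit(config: TransitConfig) -> TrajectoryRecord:
    """Simulate one full transit and record the trajectory."""
    geometry = config.geometry()
    lat_cfg = config.lattice_config()
    dp, f_steady = _steady_flow(config, geometry)
    fieldobj = geometry.make_field(lat_cfg, dp=dp, lam=config.lam)
    fieldobj.visc_every = config.visc_every
    fieldobj.f[:] = f_steady
    fieldobj.refresh_macros()

    # compound cell: concentric spherical membranes, stress-free reference
    a = config.a
    x0 = config.default_release_x()
    centre = np.array([x0, config.d_oc_y * config.l, config.d_oc_z * config.l])
    cell_mesh = make_sphere_mesh(config.mesh_subdivisions, a, centre)
    nuc_mesh = make_sphere_mesh(max(config.mesh_subdivisions - 1, 1),
                                0.5 * a, centre)
    cell = Membrane(cell_mesh, Gs=config.Gs, C=config.groups.C,
                    mu_s=config.mu_s, kc=config.kc)
    nucleus = Membrane(nuc_mesh, Gs=2.0 * config.Gs, C=config.groups.C,
                       mu_s=0.0, kc=0.001 * 2.0 * config.Gs * (0.5 * a) ** 2)

    dt = config.dt
    t_scale = config.l / config.U
    max_steps = int(config.max_tstar * t_scale / dt)
    hl = 0.5 * config.l

    ts, cents, DIs, DXZs, vc, vn, contours = [], [], [], [], [], [], []
    events: dict = {}
    steady_samples: list[tuple[float, float]] = []  # (x, DI) per 0.5 l
    last_steady_x = centre[0]
    k_strain = config.strain_window_steps()
    snap_age = 0

    update_indicator(fieldobj, cell_mesh)
    for step in range(max_steps):
        if step % config.indicator_every == 0 and step > 0:
            update_indicator(fieldobj, cell_mesh)
        fc = cell.forces(max(snap_age, 1) * dt)
        fn = nucleus.forces(dt)
        fieldobj.force[:] = 0.0
        spread_forces(fieldobj, cell_mesh.vertices, fc)
        spread_forces(fieldobj, nuc_mesh.vertices, fn)
        fieldobj.step(1)
        vcell = interpolate_velocity(fieldobj, cell_mesh.vertices)
        vnuc = interpolate_velocity(fieldobj, nuc_mesh.vertices)
        cell_mesh.vertices += vcell * dt
        nuc_mesh.vertices += vnuc * dt
        nucleus.advance()
        snap_age += 1
        if snap_age >= k_strain:
            cell.advance()
            snap_age = 0

        if step % 200 == 0:
            fieldobj.check_stability()
            if not np.all(np.isfinite(cell_mesh.vertices)):
                raise RuntimeError(
                    "membrane vertices diverged; reduce dt_safety"
                )

        if step % config.record_every == 0:
            t = (step + 1) * dt
            cen = cell_mesh.centroid()
            contour = project_xz(cell_mesh)
            di = deformation_index(contour)
            dxz = taylor_parameter(contour)
            ts.append(t)
            cents.append(cen)
            DIs.append(di)
            DXZs.append(dxz)
            vc.append(cell.volume())
            vn.append(nucleus.volume())
            contours.append(contour.points * 1e6)

            if config.kind == "cross_slot":
                front = cell_mesh.vertices[:, 0].max()
                if "entry_t" not in events and front >= -hl:
                    events["entry_t"] = t
                if "entry_t" in events:
                    d_stag = float(np.linalg.norm(cen[[0, 2]]))
                    if ("closest_t" not in events
                            or d_stag < events["closest_d"]):
                        events["closest_t"] = t
                        events["closest_d"] = d_stag
                    vx = cell_mesh.vertices[:, 0]
                    vz = cell_mesh.vertices[:, 2]
                    outside = np.all(
                        (np.abs(vx) > hl) | (np.abs(vz) > hl)
                    ) and np.abs(cen[2]) > hl
                    if outside and "exit_t" not in events:
                        events["exit_t"] = t
                        if step > 0:
                            break
            else:
                # steady-shape detector, sampled per 0.5 l of travel
                if cen[0] - last_steady_x >= 0.5 * config.l:
                    last_steady_x = cen[0]
                    steady_samples.append((cen[0], di))
                    if len(steady_samples) >= 3:
                        (x2, di2), (x0s, di0) = steady_samples[-1], steady_samples[-3]
                        if (cen[0] > 2 * config.l
                                and abs(di2 - di0) < config.steady_dDI
                                * (x2 - x0s) / config.l):
                            events["steady_t"] = t
                            break
                if cen[0] > config.straight_len - 3.0 * a:
                    break

    rec = TrajectoryRecord(
        t=np.asarray(ts),
        tstar=np.asarray(ts) / t_scale,
        centroid=np.asarray(cents),
        DI=np.asarray(DIs),
        DXZ=np.asarray(DXZs),
        vol_cell=np.asarray(vc),
        vol_nucleus=np.asarray(vn),
        contours=contours,
        events=events,
        meta={
            "dp": dp, "dt": dt, "a": a, "Gs": config.Gs,
            "Ks": config.Ks, "mu_s": config.mu_s,
            "release_x": x0, "kind": config.kind,
            "groups": vars(config.groups).copy(),
            "nodes_per_l": config.nodes_per_l,
        },
    )
    return rec


def cached_transit(config: TransitConfig) -> TrajectoryRecord:
    """Run (or reload) a transit, content-addressed by its configuration."""
    key = {
        "what": "transit", **config._flow_key(),
        "groups": [config.groups.Ca, config.groups.C, config.groups.eta,
                   config.groups.lam, config.groups.confinement,
                   config.groups.an_over_a],
        "d": [config.d_oc_y, config.d_oc_z],
        "mesh": config.mesh_subdivisions,
        "release_x": config.default_release_x(),
        "record_every": config.record_every,
        "max_tstar": config.max_tstar,
    }
    if config.use_cache:
        hit = _cache.load(key)
        if hit is not None:
            ncon = int(hit["n_contours"])
            contours = [hit[f"contour_{i}"] for i in range(ncon)]
            import json

            return TrajectoryRecord(
                t=hit["t"], tstar=hit["tstar"], centroid=hit["centroid"],
                DI=hit["DI"], DXZ=hit["DXZ"], vol_cell=hit["vol_cell"],
                vol_nucleus=hit["vol_nucleus"], contours=contours,
                events=json.loads(str(hit["events"])),
                meta=json.loads(str(hit["meta"])),
            )
    rec = run_transit(config)
    if config.use_cache:
        import json

        payload = {
            "t": rec.t, "tstar": rec.tstar, "centroid": rec.centroid,
            "DI": rec.DI, "DXZ": rec.DXZ, "vol_cell": rec.vol_cell,
            "vol_nucleus": rec.vol_nucleus,
            "n_contours": np.int64(len(rec.contours)),
            "events": np.str_(json.dumps(rec.events)),
            "meta": np.str_(json.dumps(rec.meta)),
        }
        for i, c in enumerate(rec.contours):
            payload[f"contour_{i}"] = c
        _cache.save(key, payload)
    return rec


def residence_time(record: TrajectoryRecord, l: float, U: float) -> float:
    """Dimensionless time the cell spends inside the cross-slot region.

    t* runs from the entry event (cell forefront crossing x = -l/2) to the
    complete exit (all vertices outside the central square).  Returns
    ``math.inf`` when the cell never exits (e.g. trapped on the centreline).
    """
    if "entry_t" not in record.events:
        raise ValueError("record has no cross-slot entry event")
    if "exit_t" not in record.events:
        return math.inf
    return (record.events["exit_t"] - record.events["entry_t"]) / (l / U)
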