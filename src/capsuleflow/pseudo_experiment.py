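"""Synthetic observations and forward-simulation libraries.

A pseudo-experiment is a reduced-resolution forward simulation at known
parameters whose outputs (contour series, deformation series, trajectory)
stand in for a recorded cell, optionally with seeded Gaussian noise on the
contour points.  It closes the loop for the inverse-fitting machinery: a
noiseless on-grid pseudo-experiment must be recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield, replace

import numpy as np

from .io_utils import provenance_header
from .params import DimensionlessGroups
from .shape_metrics import ContourProfile, deformation_index, taylor_parameter
from .transit_simulation import TransitConfig, TrajectoryRecord, cached_transit

__all__ = ["PseudoExperiment", "make_pseudo_experiment",
           "build_steady_library", "build_eta_library",
           "build_offcenter_library"]


@dataclass
class PseudoExperiment:
    """Synthetic stand-in for one recorded cell transit."""

    true_params: dict
    noise_sigma: float  # um, on contour points
    seed: int
    t: np.ndarray
    tstar: np.ndarray
    centroid: np.ndarray  # (n, 3) m
    contours: list  # (k, 2) um
    DI: np.ndarray
    DXZ: np.ndarray
    events: dict
    provenance: dict = dfield(default_factory=dict)

    @property
    def steady_contour(self) -> np.ndarray:
        return self.contours[-1]

    @property
    def steady_DI(self) -> float:
        return float(self.DI[-1])

    def z_trajectory(self, l: float, U: float):
        """(t*, z) with t* = 0 at cross-slot entry; z in um."""
        if "entry_t" not in self.events:
            raise ValueError("no cross-slot entry event recorded")
        ts = (self.t - self.events["entry_t"]) / (l / U)
        return ts, self.centroid[:, 2] * 1e6

    def deformation_series(self, kind: str, l: float, U: float):
        """Stage-2 observation: DI vs x/l (constricted/straight) or D_XZ
        vs entry-relative t* (cross-slot)."""
        if kind == "cross_slot":
            ts = (self.t - self.events["entry_t"]) / (l / U)
            return ts, self.DXZ
        return self.centroid[:, 0] / l, self.DI


def make_pseudo_experiment(config: TransitConfig, noise_sigma: float = 0.0,
                           seed: int = 0) -> PseudoExperiment:
    """Forward-simulate ``config`` and package it as an observation.

    ``noise_sigma`` (um) adds seeded Gaussian noise to every contour point;
    the DI/D_XZ series are then recomputed from the noisy contours, so a
    zero-noise pseudo-experiment is bit-identical to the forward record.
    """
    rec: TrajectoryRecord = cached_transit(config)
    contours = [np.asarray(c, dtype=float) for c in rec.contours]
    DI = rec.DI.copy()
    DXZ = rec.DXZ.copy()
    if noise_sigma > 0.0:
        rng = np.random.default_rng(seed)
        noisy = []
        for c in contours:
            noisy.append(c + rng.normal(0.0, noise_sigma, c.shape))
        contours = noisy
        DI = np.array([deformation_index(ContourProfile(c)) for c in contours])
        DXZ = np.array([taylor_parameter(ContourProfile(c)) for c in contours])
    true_params = {
        "Ca": config.groups.Ca, "C": config.groups.C,
        "eta": config.groups.eta, "d_oc_z": config.d_oc_z,
    }
    return PseudoExperiment(
        true_params=true_params, noise_sigma=noise_sigma, seed=seed,
        t=rec.t, tstar=rec.tstar, centroid=rec.centroid,
        contours=contours, DI=DI, DXZ=DXZ, events=rec.events,
        provenance=provenance_header(
            {**true_params, "noise_sigma": noise_sigma}, seed=seed),
    )


def _with_groups(config: TransitConfig, **updates) -> TransitConfig:
    groups = DimensionlessGroups(**{**vars(config.groups), **updates})
    return replace(config, groups=groups)


def build_steady_library(base: TransitConfig, Ca_values, C_values) -> dict:
    """(Ca, C) -> (steady DI, steady contour um) from hyperelastic runs."""
    library = {}
    for Ca in Ca_values:
        for C in C_values:
            cfg = _with_groups(base, Ca=float(Ca), C=float(C), eta=0.0)
            rec = cached_transit(cfg)
            library[(float(Ca), float(C))] = (
                float(rec.DI[-1]), np.asarray(rec.contours[-1]))
    return library


def build_eta_library(base: TransitConfig, eta_values) -> dict:
    """eta -> deformation series at fixed (Ca, C)."""
    library = {}
    for eta in eta_values:
        cfg = _with_groups(base, eta=float(eta))
        rec = cached_transit(cfg)
        if base.kind == "cross_slot":
            ts = (rec.t - rec.events["entry_t"]) / (base.l / base.U)
            library[float(eta)] = (ts, rec.DXZ)
        else:
            library[float(eta)] = (rec.centroid[:, 0] / base.l, rec.DI)
    return library


def build_offcenter_library(base: TransitConfig, d_values) -> dict:
    """d_oc (fraction of l) -> (t*, z um) hyperelastic trajectories."""
    library = {}
    for d in d_values:
        cfg = replace(_with_groups(base, eta=0.0), d_oc_z=float(d))
        rec = cached_transit(cfg)
        ts = (rec.t - rec.events["entry_t"]) / (base.l / base.U)
        library[float(d)] = (ts, rec.centroid[:, 2] * 1e6)
    return library
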